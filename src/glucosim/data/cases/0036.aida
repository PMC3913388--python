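# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0036
name: Miriam Stanhope
description: This woman with insulin-dependent diabetes is on Actrapid with meals and Ultratard at bedtime. She is adjusting to a new routine after changing jobs. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 66 kg
meal: 10:30 10
meal: 12:30 45
meal: 18:30 45
meal: 22:00 15
insulin: Actrapid
injection: 07:30 8
injection: 12:30 6
injection: 18:30 6
insulin: Ultratard
injection: 22:30 16
rtg: normal
ccr: normal
hepatic: normal
peripheral: high
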