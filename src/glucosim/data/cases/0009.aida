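# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0009
name: Fiona McAllister
description: This woman with insulin-dependent diabetes is on Actrapid with meals and Humulin Zn at bedtime. She is adjusting to a new routine after changing jobs. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 82 kg
meal: 07:30 30
meal: 10:30 10
meal: 12:30 40
meal: 15:30 10
meal: 18:30 40
insulin: Actrapid
injection: 07:30 10
injection: 12:30 8
injection: 18:30 8
insulin: Humulin Zn
injection: 22:30 22
rtg: low
ccr: low
hepatic: high
peripheral: low
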