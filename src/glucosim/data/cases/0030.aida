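# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0030
name: Lucia Ferreira
description: This woman with insulin-dependent diabetes is on Actrapid with meals and Ultratard at bedtime. She is keen to see what happens when meals are moved or resized. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 66 kg
meal: 07:30 35
meal: 10:30 10
meal: 12:30 40
meal: 15:30 15
meal: 18:30 45
meal: 22:00 15
insulin: Actrapid
injection: 07:30 6
injection: 12:30 5
injection: 18:30 5
insulin: Ultratard
injection: 22:30 14
rtg: low
ccr: normal
hepatic: low
peripheral: normal
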