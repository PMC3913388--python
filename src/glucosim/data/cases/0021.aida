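# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0021
name: Dorothy Ainsworth
description: This woman with insulin-dependent diabetes is on Actrapid with meals and Insulatard at bedtime. She is finding the evening readings creep up after supper. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 57 kg
meal: 07:30 40
meal: 10:30 10
meal: 15:30 15
meal: 18:30 45
meal: 22:00 15
insulin: Actrapid
injection: 07:30 8
injection: 12:30 6
injection: 18:30 6
insulin: Insulatard
injection: 22:30 16
rtg: low
ccr: low
hepatic: high
peripheral: high
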