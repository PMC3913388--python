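# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0027
name: Bruce Tanaka
description: This man with insulin-dependent diabetes is on Humulin S with meals and Humulin Zn at bedtime. He is finding the evening readings creep up after supper. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 77 kg
meal: 10:30 10
meal: 12:30 35
meal: 15:30 10
meal: 22:00 15
insulin: Humulin S
injection: 07:30 12
injection: 12:30 9
injection: 18:30 9
insulin: Humulin Zn
injection: 22:30 24
rtg: high
ccr: low
hepatic: normal
peripheral: low
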