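# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0012
name: Gavin Proudfoot
description: This man with insulin-dependent diabetes is on Humulin S with meals and Insulatard at bedtime. He is finding the evening readings creep up after supper. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 83 kg
meal: 07:30 35
meal: 10:30 10
meal: 12:30 45
meal: 22:00 15
insulin: Humulin S
injection: 07:30 11
injection: 12:30 8
injection: 18:30 8
insulin: Insulatard
injection: 22:30 23
rtg: high
ccr: low
hepatic: high
peripheral: high
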