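# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0039
name: Raymond Chu
description: This man with insulin-dependent diabetes is on Velosulin with meals and Insulatard at bedtime. He is wondering whether redistributing the insulin doses would smooth the profile. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 73 kg
meal: 10:30 15
meal: 12:30 55
meal: 15:30 15
meal: 22:00 20
insulin: Velosulin
injection: 07:30 11
injection: 12:30 8
injection: 18:30 8
insulin: Insulatard
injection: 22:30 22
rtg: normal
ccr: normal
hepatic: low
peripheral: high
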