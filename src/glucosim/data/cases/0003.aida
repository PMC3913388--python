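# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0003
name: Anna Kowalska
description: This woman with insulin-dependent diabetes is on Humulin S with meals and Insulatard at bedtime. She is wondering whether redistributing the insulin doses would smooth the profile. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 63 kg
meal: 07:30 35
meal: 10:30 10
meal: 12:30 40
meal: 15:30 10
meal: 18:30 40
insulin: Humulin S
injection: 07:30 8
injection: 12:30 6
injection: 18:30 6
insulin: Insulatard
injection: 22:30 15
rtg: normal
ccr: normal
hepatic: low
peripheral: high
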