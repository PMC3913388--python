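# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0006
name: Colin Whitfield
description: This man with insulin-dependent diabetes is on Humulin S with meals and Humulin Zn at bedtime. He is wondering whether redistributing the insulin doses would smooth the profile. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 73 kg
meal: 10:30 10
meal: 12:30 45
meal: 18:30 45
meal: 22:00 15
insulin: Humulin S
injection: 07:30 8
injection: 12:30 6
injection: 18:30 6
insulin: Humulin Zn
injection: 22:30 18
rtg: low
ccr: low
hepatic: high
peripheral: high
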