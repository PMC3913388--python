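# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0015
name: Priya Raman
description: This woman with insulin-dependent diabetes is on Actrapid with meals and Humulin Zn at bedtime. She is wondering whether redistributing the insulin doses would smooth the profile. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 75 kg
meal: 10:30 10
meal: 12:30 45
meal: 15:30 15
meal: 18:30 45
insulin: Actrapid
injection: 07:30 8
injection: 12:30 6
injection: 18:30 6
insulin: Humulin Zn
injection: 22:30 16
rtg: low
ccr: normal
hepatic: high
peripheral: low
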