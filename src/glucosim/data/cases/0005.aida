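# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0005
name: Sarah Bennett
description: This woman with insulin-dependent diabetes is on twice daily Actrapid and Humulin I. She is wondering whether redistributing the insulin doses would smooth the profile. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 69 kg
meal: 07:30 30
meal: 10:30 10
meal: 12:30 40
meal: 15:30 10
meal: 18:30 40
meal: 22:00 15
insulin: Actrapid
injection: 07:30 10
injection: 18:00 6
insulin: Humulin I
injection: 07:30 14
injection: 22:00 10
rtg: high
ccr: normal
hepatic: normal
peripheral: low
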