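# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0020
name: Oliver Pemberton
description: This man with insulin-dependent diabetes is on twice daily Actrapid and Humulin I. He is wondering whether redistributing the insulin doses would smooth the profile. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 88 kg
meal: 07:30 40
meal: 10:30 15
meal: 12:30 50
meal: 15:30 15
meal: 18:30 50
meal: 22:00 20
insulin: Actrapid
injection: 07:30 13
injection: 18:00 8
insulin: Humulin I
injection: 07:30 18
injection: 22:00 13
rtg: high
ccr: normal
hepatic: normal
peripheral: normal
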