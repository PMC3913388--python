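# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0032
name: Harriet Snow
description: This woman with insulin-dependent diabetes is on twice daily Humulin S and Insulatard. She is troubled by high blood glucose readings before breakfast. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 69 kg
meal: 07:30 50
meal: 12:30 55
meal: 15:30 15
meal: 18:30 60
meal: 22:00 20
insulin: Humulin S
injection: 07:30 8
injection: 18:00 5
insulin: Insulatard
injection: 07:30 11
injection: 22:00 8
rtg: high
ccr: normal
hepatic: normal
peripheral: high
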