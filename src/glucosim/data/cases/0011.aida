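# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0011
name: Rachel Ormond
description: This woman with insulin-dependent diabetes is on twice daily Humulin S and Protaphane. She is troubled by high blood glucose readings before breakfast. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 62 kg
meal: 10:30 10
meal: 15:30 15
meal: 18:30 45
meal: 22:00 15
insulin: Humulin S
injection: 07:30 8
injection: 18:00 5
insulin: Protaphane
injection: 07:30 12
injection: 22:00 9
rtg: normal
ccr: normal
hepatic: normal
peripheral: high
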