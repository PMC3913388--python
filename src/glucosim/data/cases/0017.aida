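# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0017
name: Celia Thornbury
description: This woman with insulin-dependent diabetes is on twice daily Humulin S and Protaphane. She is troubled by high blood glucose readings before breakfast. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 94 kg
meal: 07:30 50
meal: 10:30 15
meal: 12:30 60
meal: 15:30 20
meal: 22:00 20
insulin: Humulin S
injection: 07:30 14
injection: 18:00 9
insulin: Protaphane
injection: 07:30 20
injection: 22:00 14
rtg: low
ccr: low
hepatic: high
peripheral: low
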