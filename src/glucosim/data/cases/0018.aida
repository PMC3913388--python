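# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0018
name: Martin Drummond
description: This man with insulin-dependent diabetes is on Velosulin with meals and Humulin Zn at bedtime. He is troubled by high blood glucose readings before breakfast. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 90 kg
meal: 10:30 15
meal: 15:30 15
meal: 18:30 50
meal: 22:00 20
insulin: Velosulin
injection: 07:30 12
injection: 12:30 9
injection: 18:30 9
insulin: Humulin Zn
injection: 22:30 25
rtg: high
ccr: normal
hepatic: normal
peripheral: normal
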