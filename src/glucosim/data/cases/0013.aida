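# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0013
name: Ingrid Larsen
description: This woman with insulin-dependent diabetes is on a twice daily premixed (Humulin M3) regimen. She is keen to see what happens when meals are moved or resized. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 56 kg
meal: 07:30 45
meal: 12:30 55
meal: 15:30 15
meal: 18:30 55
meal: 22:00 20
insulin: Humulin M3
injection: 08:00 20
injection: 18:00 13
rtg: normal
ccr: low
hepatic: high
peripheral: normal
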