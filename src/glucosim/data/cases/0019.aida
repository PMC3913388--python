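# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0019
name: Helen Castellano
description: This woman with insulin-dependent diabetes is on a twice daily premixed (Humulin M3) regimen. She is keen to see what happens when meals are moved or resized. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 65 kg
meal: 10:30 10
meal: 12:30 40
meal: 15:30 15
meal: 22:00 15
insulin: Humulin M3
injection: 08:00 25
injection: 18:00 16
rtg: low
ccr: normal
hepatic: low
peripheral: low
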