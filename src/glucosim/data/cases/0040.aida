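# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0040
name: Gwen Harlow
description: This woman with insulin-dependent diabetes is on a twice daily premixed (Insuman Comb 25) regimen. She is keen to see what happens when meals are moved or resized. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 63 kg
meal: 07:30 45
meal: 10:30 15
meal: 12:30 55
meal: 15:30 15
insulin: Insuman Comb 25
injection: 08:00 25
injection: 18:00 16
rtg: high
ccr: normal
hepatic: normal
peripheral: high
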