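# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0034
name: June Okafor
description: This woman with insulin-dependent diabetes is on a twice daily premixed (Mixtard 30/70) regimen. She is keen to see what happens when meals are moved or resized. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 77 kg
meal: 07:30 50
meal: 10:30 15
meal: 12:30 60
meal: 15:30 20
meal: 18:30 60
meal: 22:00 25
insulin: Mixtard 30/70
injection: 08:00 23
injection: 18:00 15
rtg: high
ccr: normal
hepatic: normal
peripheral: high
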