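# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0007
name: Margaret Ellis
description: This woman with insulin-dependent diabetes is on a twice daily premixed (PenMix 20/80) regimen. She is troubled by high blood glucose readings before breakfast. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 52 kg
meal: 07:30 30
meal: 10:30 10
meal: 12:30 40
meal: 15:30 10
meal: 18:30 40
meal: 22:00 15
insulin: PenMix 20/80
injection: 08:00 16
injection: 18:00 10
rtg: low
ccr: low
hepatic: low
peripheral: low
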