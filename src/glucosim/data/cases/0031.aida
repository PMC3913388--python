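# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0031
name: Edmund Blakely
description: This man with insulin-dependent diabetes is on a twice daily premixed (Mixtard 30/70) regimen. He is adjusting to a new routine after changing jobs. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 90 kg
meal: 07:30 45
meal: 10:30 15
meal: 12:30 55
meal: 15:30 15
meal: 18:30 55
meal: 22:00 20
insulin: Mixtard 30/70
injection: 08:00 28
injection: 18:00 19
rtg: normal
ccr: normal
hepatic: normal
peripheral: low
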