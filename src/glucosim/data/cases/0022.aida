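# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0022
name: Frank Ziegler
description: This man with insulin-dependent diabetes is on a twice daily premixed (Insuman Comb 25) regimen. He is adjusting to a new routine after changing jobs. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 89 kg
meal: 07:30 30
meal: 10:30 10
meal: 12:30 35
meal: 15:30 10
meal: 22:00 15
insulin: Insuman Comb 25
injection: 08:00 35
injection: 18:00 23
rtg: normal
ccr: low
hepatic: low
peripheral: low
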