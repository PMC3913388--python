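# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0016
name: Victor Osei
description: This man with insulin-dependent diabetes is on a twice daily premixed (Insuman Comb 25) regimen. He is finding the evening readings creep up after supper. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 78 kg
meal: 07:30 35
meal: 10:30 10
meal: 12:30 40
meal: 15:30 15
meal: 18:30 45
meal: 22:00 15
insulin: Insuman Comb 25
injection: 08:00 28
injection: 18:00 18
rtg: low
ccr: normal
hepatic: low
peripheral: high
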