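# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0028
name: Sofia Marchetti
description: This woman with insulin-dependent diabetes is on a twice daily premixed (Insuman Comb 25) regimen. She is finding the evening readings creep up after supper. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 76 kg
meal: 07:30 45
meal: 10:30 15
meal: 12:30 55
meal: 15:30 15
meal: 18:30 60
meal: 22:00 20
insulin: Insuman Comb 25
injection: 08:00 26
injection: 18:00 17
rtg: normal
ccr: normal
hepatic: normal
peripheral: low
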