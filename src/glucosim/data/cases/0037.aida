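# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0037
name: Angus Ferguson
description: This man with insulin-dependent diabetes is on a twice daily premixed (Insuman Comb 25) regimen. He is experiencing late-morning dips after an active start to the day. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 67 kg
meal: 07:30 35
meal: 10:30 10
meal: 12:30 45
meal: 15:30 15
meal: 18:30 45
meal: 22:00 15
insulin: Insuman Comb 25
injection: 08:00 26
injection: 18:00 18
rtg: normal
ccr: low
hepatic: high
peripheral: low
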