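# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0004
name: Derek Mahoney
description: This man with insulin-dependent diabetes is on a twice daily premixed (PenMix 20/80) regimen. He is experiencing late-morning dips after an active start to the day. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 82 kg
meal: 07:30 30
meal: 15:30 10
meal: 18:30 40
meal: 22:00 15
insulin: PenMix 20/80
injection: 08:00 32
injection: 18:00 22
rtg: low
ccr: normal
hepatic: normal
peripheral: low
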