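# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0014
name: Stanley Hobbs
description: This man with insulin-dependent diabetes is on twice daily Actrapid and Protaphane. He is experiencing late-morning dips after an active start to the day. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 76 kg
meal: 10:30 15
meal: 12:30 45
meal: 15:30 15
meal: 18:30 50
meal: 22:00 20
insulin: Actrapid
injection: 07:30 12
injection: 18:00 8
insulin: Protaphane
injection: 07:30 18
injection: 22:00 12
rtg: high
ccr: normal
hepatic: low
peripheral: normal
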