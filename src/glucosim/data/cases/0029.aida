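# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0029
name: Wallace Greene
description: This man with insulin-dependent diabetes is on twice daily Actrapid and Protaphane. He is wondering whether redistributing the insulin doses would smooth the profile. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 75 kg
meal: 07:30 45
meal: 12:30 55
meal: 15:30 15
meal: 22:00 20
insulin: Actrapid
injection: 07:30 11
injection: 18:00 6
insulin: Protaphane
injection: 07:30 15
injection: 22:00 11
rtg: low
ccr: low
hepatic: high
peripheral: high
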