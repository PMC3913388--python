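# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0025
name: Eileen Murtagh
description: This woman with insulin-dependent diabetes is on a twice daily premixed (PenMix 20/80) regimen. She is wondering whether redistributing the insulin doses would smooth the profile. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 83 kg
meal: 07:30 45
meal: 10:30 15
meal: 15:30 15
meal: 18:30 60
meal: 22:00 20
insulin: PenMix 20/80
injection: 08:00 31
injection: 18:00 20
rtg: low
ccr: normal
hepatic: normal
peripheral: high
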