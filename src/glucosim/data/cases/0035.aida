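# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0035
name: Leonard Quayle
description: This man with insulin-dependent diabetes is on twice daily Humulin S and Humulin I. He is adjusting to a new routine after changing jobs. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 58 kg
meal: 07:30 35
meal: 10:30 10
meal: 12:30 45
meal: 15:30 15
meal: 18:30 45
meal: 22:00 15
insulin: Humulin S
injection: 07:30 8
injection: 18:00 5
insulin: Humulin I
injection: 07:30 12
injection: 22:00 8
rtg: high
ccr: normal
hepatic: low
peripheral: normal
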