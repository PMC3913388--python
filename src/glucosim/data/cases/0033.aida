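# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0033
name: Pavel Horak
description: This man with insulin-dependent diabetes is on Humulin S with meals and Humulin Zn at bedtime. He is experiencing late-morning dips after an active start to the day. Use the simulator to explore how dose and meal changes alter the 24-hour blood glucose profile.
weight: 76 kg
meal: 07:30 45
meal: 10:30 15
meal: 12:30 55
meal: 15:30 15
meal: 22:00 20
insulin: Humulin S
injection: 07:30 10
injection: 12:30 8
injection: 18:30 8
insulin: Humulin Zn
injection: 22:30 21
rtg: high
ccr: low
hepatic: normal
peripheral: low
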