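# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0010
name: Hugh Allibaster
description: This man with insulin-dependent diabetes injects short-acting Actrapid in the morning and evening with long-acting Ultralente at night. His blood glucose profile runs persistently above the normoglycaemic band and his predicted HbA1c is elevated. Consider increasing the evening short-acting dose, then the night-time long-acting dose, and finally trimming supper and the bedtime snack - watching the predicted HbA1c improve step by step.
weight: 68 kg
meal: 08:00 35
meal: 10:30 15
meal: 12:30 45
meal: 15:30 10
meal: 19:00 40
meal: 22:30 10
insulin: Actrapid
injection: 07:30 6
injection: 19:30 4
insulin: Ultralente Iletin I
injection: 23:00 8
rtg: normal
ccr: normal
hepatic: normal
peripheral: low
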