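# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0001
name: Joy Wilson
description: This woman with insulin-dependent diabetes is on a classical basal-bolus regimen: short-acting insulin with each main meal and an isophane dose at bedtime. Her control is reasonable but her pre-lunch readings run a little high. An ideal introductory case: try shifting a few grams of carbohydrate or a unit or two of insulin and watch the whole day respond.
weight: 58 kg
meal: 07:30 30
meal: 10:30 10
meal: 12:30 45
meal: 15:30 10
meal: 18:30 45
meal: 22:00 15
insulin: Actrapid
injection: 07:30 6
injection: 12:30 5
injection: 18:30 6
insulin: Insulatard
injection: 22:00 12
rtg: normal
ccr: normal
hepatic: normal
peripheral: normal
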