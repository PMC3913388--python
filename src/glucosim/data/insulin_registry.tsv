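# Insulin preparation registry: name <TAB> category <TAB> detail
# detail = absorption class for short/intermediate/long,
#          percent_short/intermediate_component_class for biphasic premixes.
# Classic (pre-analogue) brands: 10 short-, 19 intermediate-, 4 long-acting
# and 18 biphasic entries.  The 19 intermediate brands are split 10 NPH-like
# (isophane suspensions) and 9 Lente-like (zinc suspensions).
Actrapid	short	ACTRAPID_LIKE
Humulin S	short	ACTRAPID_LIKE
Velosulin	short	ACTRAPID_LIKE
Insuman Rapid	short	ACTRAPID_LIKE
Hypurin Porcine Neutral	short	ACTRAPID_LIKE
Hypurin Bovine Neutral	short	ACTRAPID_LIKE
Pork Actrapid	short	ACTRAPID_LIKE
Iletin II Regular	short	ACTRAPID_LIKE
Novolin R	short	ACTRAPID_LIKE
Humaject S	short	ACTRAPID_LIKE
Insulatard	intermediate	NPH_LIKE
Humulin I	intermediate	NPH_LIKE
Protaphane	intermediate	NPH_LIKE
Insuman Basal	intermediate	NPH_LIKE
Hypurin Porcine Isophane	intermediate	NPH_LIKE
Hypurin Bovine Isophane	intermediate	NPH_LIKE
Pork Insulatard	intermediate	NPH_LIKE
Iletin II NPH	intermediate	NPH_LIKE
Novolin N	intermediate	NPH_LIKE
Humaject I	intermediate	NPH_LIKE
Monotard	intermediate	LENTE_LIKE
Humulin Lente	intermediate	LENTE_LIKE
Lentard MC	intermediate	LENTE_LIKE
Hypurin Bovine Lente	intermediate	LENTE_LIKE
Semitard MC	intermediate	LENTE_LIKE
Novolin L	intermediate	LENTE_LIKE
Lente Iletin I	intermediate	LENTE_LIKE
Lente Iletin II	intermediate	LENTE_LIKE
Semilente MC	intermediate	LENTE_LIKE
Ultratard	long	ULTRALENTE_LIKE
Humulin Zn	long	ULTRALENTE_LIKE
Hypurin Bovine PZI	long	ULTRALENTE_LIKE
Ultralente Iletin I	long	ULTRALENTE_LIKE
Mixtard 10/90	biphasic	10/NPH_LIKE
Mixtard 20/80	biphasic	20/NPH_LIKE
Mixtard 30/70	biphasic	30/NPH_LIKE
Mixtard 40/60	biphasic	40/NPH_LIKE
Mixtard 50/50	biphasic	50/NPH_LIKE
PenMix 10/90	biphasic	10/NPH_LIKE
PenMix 20/80	biphasic	20/NPH_LIKE
PenMix 30/70	biphasic	30/NPH_LIKE
PenMix 40/60	biphasic	40/NPH_LIKE
PenMix 50/50	biphasic	50/NPH_LIKE
Humulin M1	biphasic	10/NPH_LIKE
Humulin M2	biphasic	20/NPH_LIKE
Humulin M3	biphasic	30/NPH_LIKE
Humulin 50/50	biphasic	50/NPH_LIKE
Humulin 70/30	biphasic	30/NPH_LIKE
Insuman Comb 15	biphasic	15/NPH_LIKE
Insuman Comb 25	biphasic	25/NPH_LIKE
Insuman Comb 50	biphasic	50/NPH_LIKE
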