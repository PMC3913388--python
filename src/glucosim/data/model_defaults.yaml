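# Default simulator configuration.  Everything here can be overridden by a
# user config file passed to glucosim.config.load_config / the CLI --config
# flag.  All values are validated against their type invariants at load.

# HbA1c regression on mean blood glucose (mg/dL):
#   classic: HbA1c = (mean + 86) / 33.3
#   eag:     HbA1c = (mean + 46.7) / 28.7   (inverse of eAG = 28.7*A1c - 46.7)
hba1c_model: classic

# Sigmoid absorption parameters per insulin class:
#   cumulative fraction F(t) = t^s / (T50^s + t^s), T50(D) = a*D + b (hours).
# Chosen so peak order short < NPH <= Lente < UltraLente holds.
class_params:
  ACTRAPID_LIKE: {shape_s: 2.0, t50_slope_a: 0.05, t50_intercept_b: 1.5}
  NPH_LIKE: {shape_s: 2.0, t50_slope_a: 0.14, t50_intercept_b: 5.0}
  LENTE_LIKE: {shape_s: 2.4, t50_slope_a: 0.15, t50_intercept_b: 6.5}
  ULTRALENTE_LIKE: {shape_s: 2.5, t50_slope_a: 0.13, t50_intercept_b: 13.0}

# Overrides for glucosim.model.ModelConstants fields, e.g.:
#   constants:
#     km_mmol_per_l: 12.0
#     nhgb_insulin_nodes: [...]
# An empty mapping keeps the documented defaults (including the packaged
# NHGB grid, whose monotonicity is machine-checked on construction).
constants: {}
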