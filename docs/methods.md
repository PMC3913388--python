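# Methods

## Scope and intent

glucosim is an educational simulator: it reproduces the *qualitative*
pharmacology of insulin and diet adjustment in insulin-dependent diabetes
(directions, time courses, orders of magnitude), not any individual
patient's glycaemia. It must never be used for therapy planning. The model
deliberately omits endogenous insulin secretion, counter-regulation
(glucagon/adrenaline rescue from hypoglycaemia), exercise, stress, illness
and carbohydrate-type effects.

## Subcutaneous insulin absorption

The cumulative absorbed fraction of a dose D injected subcutaneously is
the sigmoid

    F(t) = t^s / (T50(D)^s + t^s),    T50(D) = a·D + b,

with the dose-dependent half-absorption time T50 making kinetics nonlinear
in D: larger depots absorb disproportionately slowly. This is the
classical empirical description of depot absorption for the pre-analogue
preparations covered here. Per-class defaults (editable in
`data/model_defaults.yaml`):

| class            | s   | a (h/IU) | b (h) | role                    |
|------------------|-----|----------|-------|-------------------------|
| ACTRAPID_LIKE    | 2.0 | 0.05     | 1.5   | soluble short-acting    |
| NPH_LIKE         | 2.0 | 0.14     | 5.0   | isophane intermediate   |
| LENTE_LIKE       | 2.4 | 0.15     | 6.5   | zinc-suspension interm. |
| ULTRALENTE_LIKE  | 2.5 | 0.13     | 13.0  | long-acting             |

The exact constants used by the historical engine this package emulates
were never published alongside it; these values are stand-ins from the same
model family, chosen once so that the plasma peak ordering
short < NPH ≤ Lente < UltraLente holds and absorption mass closes to the
dose within 1% over the precompute horizon. They were not revisited after
testing.

Plasma insulin I (IU in the compartment) obeys dI/dt = D·F'(t) − k_e·I
with elimination k_e = 5.4 h⁻¹; the effect compartment ("active" insulin,
the series that actually drives the glucose fluxes) lags first-order behind
plasma with k_act = 1.0 h⁻¹ (~1 h effect delay, the usual
effect-compartment order of magnitude — a much slower transfer would make
the active series flat and the model insensitive to injection timing).
Concentrations are obtained at simulation time as I·1000/(V_i·W) mU/L with
V_i = 0.142 L/kg.

## Lookup tables and the periodic day

Doses 0–40 IU (41 rows) and meal loads 0–80 g (81 rows) are precomputed on
a 15-minute grid (97 points, 0–24 h, point 96 duplicating point 0). Each
insulin row is integrated at 1-minute Euler steps over a 144 h horizon —
long enough that the slowest class at 40 IU leaves <0.5% of its dose in the
depot — then *folded* onto the 24 h grid: the folded value at clock offset
j is Σ_k series[j + 96k], i.e. the steady state seen when the same
injection repeats daily. Superposition of a regimen is then a circular
shift and sum of table rows; tails past midnight wrap to the morning by
construction. Dose and gram offsets are rounded to the nearest integer row
(no interpolation), mirroring the integer file-offset indexing of the
original storage format. The nine ASCII files (`Actrapid_pa`,
`Actrapid_act`, … `UltraLente_act`, `CAR`) round-trip through
`write_profile_files`/`read_profile_files` to 12 significant digits.

## Carbohydrate absorption

A meal of g grams is Ch = 5.551·g mmol glucose (180.16 g/mol). The stomach
empties it at a trapezoidal rate: linear ramps of 0.5 h up to a ceiling of
V_max = 120 mmol/h and back down, the plateau sized to the load; below the
critical load V_max·(T_asc+T_des)/2 = 60 mmol (~10.8 g) the trapezoid
degenerates to a triangle of reduced peak. The gut compartment absorbs
first-order at 1.8 h⁻¹ and that absorption flux is the gut_in term. The
day-integral of appearance equals Ch exactly up to horizon truncation
(<1%).

## Glucose fluxes

- **Renal:** zero for G ≤ RTG, GFR·(G − RTG) above, GFR = CCR·60/1000 L/h.
- **Peripheral:** (70 + S_p·4.0·I_a) · G/(10+G) mmol/h. The
  insulin-independent ceiling (70 mmol/h) and insulin slope (4.0 mmol/h per
  mU/L per unit S_p) are calibrated once so that a typical 40 IU / 180 g
  day with normal sensitivities balances near 7 mmol/L.
- **NHGB:** bilinear interpolation over a monotone grid on
  (S_h·I_a mU/L) × (G mmol/L) nodes, generated from
  P(x) = 50/(1+x/15) − (0.6 + 2.2·x/(x+15))·G and shipped as explicit node
  values. Production ≈ 46 mmol/h at zero insulin and euglycaemia; crossing
  to net uptake at high insulin. Monotone non-increase along both axes is
  machine-checked whenever constants are constructed, so a user-supplied
  grid cannot silently invert the liver's pharmacology. Inputs beyond the
  grid hull are clamped, never extrapolated.

Physiology presets (three categories per parameter): RTG 7/9/11 mmol/L,
CCR 40/100 mL/min (no "increased" clearance preset exists), hepatic and
peripheral sensitivity 0.2/0.5/0.8.

## Integration and steady state

The glucose balance is Euler-integrated at 15-minute steps (dt is
configurable to any divisor of 15 min; insulin and gut inputs are
periodically linearly interpolated onto finer grids). Starting from
7.0 mmol/L everywhere, the day is repeated — each day starting where the
previous ended — until the maximum pointwise change between consecutive
days is below 0.01 mmol/L (cap 50 iterations; failure raises, never
returns silently). Because insulin and meals are independent of G and
utilization grows with G, the day map is a contraction and convergence
typically takes 3–5 iterations. At convergence |G(0) − G(24 h)| < 0.01
mmol/L automatically. A dt = 1 min re-integration of the packaged test
cases stays within 5% pointwise of the dt = 15 min solution.

BG is floored at 0.5 mmol/L with a logged warning: the model has no
counter-regulatory rescue, so unbounded hypoglycaemia would otherwise be
possible. This is an educational-model artefact, not physiology. Meal and
injection times are snapped to the nearest grid point (logged when they
move). Weights entered in lb convert at 0.45359237 kg/lb.

## HbA1c

Mean daily BG is the arithmetic mean of the 96 interval points (the
periodic trapezoid rule). The default regression
HbA1c = (mean mg/dL + 86)/33.3 maps 200 mg/dL → 8.6%; the newer estimated
average-glucose regression (mean = 28.7·HbA1c − 46.7) is selectable with
`hba1c_model: eag`. Which averaging the historical engine used is unknown;
time-weighted and sample means coincide on a uniform periodic grid anyway.

## Case scenarios and the fixture generator

The 40 packaged cases are synthetic reconstructions (each file says so in
its header): published narrative details exist only for case 0001
("Joy Wilson", the introductory case), 0010 ("Hugh Allibaster",
short-acting + long-acting insulin with an elevated baseline HbA1c and a
guided improvement sequence) and 0026 (a twice-daily Mixtard 30/70
premixed regimen); the other 37 are authored in the same style with seeded
variety in regimen type, weight, diet and physiology categories.

`random_scenario(seed)` produces deterministic, always-valid scenarios
(weight 40–100 kg, 3–6 meals of 10–70 g at conventional times, basal-bolus
/ twice-premixed / short-only regimens, all preset categories reachable).
It emulates regimen diversity, not physiological noise: there is no
within-day variability, no measurement error and no day-to-day variation,
so passing tests demonstrate the model's internal consistency and
directional pharmacology, not fidelity to any real patient's data.

## Engine and outputs

A session keeps at most two runs (current + previous) for overlay
comparison, numbers runs from 1, and stamps a 5-digit session token into
every exported filename so concurrent sessions cannot collide. Each run
exports six two-column ASCII files (BG, plasma insulin, the four fluxes;
97 rows) with fixed-precision formatting, so repeated identical runs are
byte-identical. Across CLI invocations the previous run is rebuilt from
its exported files (the effect-compartment series is not exported and is
simply absent from rebuilt runs). Plots are PNG: 2 panels (BG +
carbohydrate bars with optional normoglycaemic bounds; plasma insulin +
injection bars) or 6 with the flux panels; current run red, previous blue.

## Known limitations

- Absolute BG/HbA1c values depend on stand-in constants; only directions
  and magnitudes-of-order are meaningful.
- Flux ceilings are not weight-scaled (weight enters through the
  distribution volumes only), so very light or heavy patients are less
  realistic.
- No insulin analogues (lispro, glargine); the registry covers classic
  preparations only.
- Integer dose/gram rounding means sub-unit adjustments have no effect.
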