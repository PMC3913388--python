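"""Compartmental glucose-insulin model for insulin-dependent diabetes.

Blood glucose G (mmol/L) in a single well-mixed space of volume Vg*weight
obeys

    dG/dt = (gut_in + NHGB - peripheral - renal) / (Vg * weight)

with four flux terms (all mmol/h):

  gut_in       glucose appearance from meals (carbohydrate lookup table)
  NHGB         net hepatic glucose balance, signed: production at low
               insulin, uptake at high insulin/glucose (interpolated grid)
  peripheral   saturable peripheral utilization, insulin-independent part
               plus a part linear in active insulin
  renal        spillover into urine above the renal glucose threshold,
               scaled by the glomerular filtration rate

Plasma and active (effect-compartment) insulin are independent of G: a
patient without endogenous secretion gets insulin only from injections, so
the insulin day profile is assembled first by periodic superposition of
precomputed table rows, then the glucose equation is Euler-integrated at
15-minute steps, repeating the same day until it closes on itself (the
periodic steady state).  Mean daily glucose finally yields an HbA1c
estimate via a linear regression on mean blood glucose.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .profiles import (
    GRID_POINTS,
    GRID_STEP_MIN,
    MAX_DOSE_IU,
    AbsorptionClass,
    AbsorptionTable,
    InsulinCategory,
    InsulinPreparation,
    ProfileError,
    biphasic_split,
    CLASS_FILE_STEM,
)

if TYPE_CHECKING:  # pragma: no cover
    from .scenario import CaseScenario

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConstants",
    "PatientParameters",
    "DaySeries",
    "DayResult",
    "PresetParameter",
    "PresetCategory",
    "ModelError",
    "ConvergenceError",
    "preset_lookup",
    "renal_excretion_rate",
    "peripheral_utilization_rate",
    "net_hepatic_balance",
    "insulin_day_profiles",
    "glucose_step",
    "simulate_day",
    "mean_bg",
    "hba1c_estimate",
    "MGDL_PER_MMOL",
    "KG_PER_LB",
]

MGDL_PER_MMOL = 18.0
KG_PER_LB = 0.45359237
MINUTES_PER_DAY = 1440


class ModelError(ValueError):
    pass


class ConvergenceError(ModelError):
    """Periodic steady state not reached within the day-iteration cap."""


def _default_nhgb_insulin_nodes() -> list[float]:
    return [0.0, 2.5, 5.0, 10.0, 20.0, 40.0, 80.0]


def _default_nhgb_glucose_nodes() -> list[float]:
    return [0.0, 2.0, 4.0, 6.0, 9.0, 12.0, 16.0, 20.0, 30.0]


def _default_nhgb_values() -> list[list[float]]:
    # production 50/(1+x/15) minus uptake slope (0.6+2.2x/(x+15))*G, rounded;
    # monotone non-increasing along both axes (checked at construction)
    xs = _default_nhgb_insulin_nodes()
    gs = _default_nhgb_glucose_nodes()
    return [[round(50.0 / (1.0 + x / 15.0) - (0.6 + 2.2 * x / (x + 15.0)) * g, 3)
             for g in gs] for x in xs]


@dataclass
class ModelConstants:
    """All rate constants, volumes and flux tables, with editable defaults.

    The defaults are stand-ins from the classical compartmental family this
    simulator belongs to; they are chosen so that a typical 40 IU / 180 g day
    balances near 7 mmol/L with normal sensitivities.
    """

    vg_l_per_kg: float = 0.22           # glucose distribution volume
    vi_l_per_kg: float = 0.142          # insulin distribution volume
    k_insulin_elim_per_h: float = 5.4   # plasma insulin elimination
    k_active_transfer_per_h: float = 1.0  # plasma -> effect compartment
    km_mmol_per_l: float = 10.0         # peripheral half-saturation
    carb_mmol_per_g: float = 5.551      # glucose, 180.16 g/mol
    gut_absorption_per_h: float = 1.8
    emptying_vmax_mmol_per_h: float = 120.0
    emptying_ramp_h: float = 0.5
    util_base_mmol_per_h: float = 70.0  # insulin-independent ceiling
    util_insulin_slope: float = 4.0     # mmol/h per mU/L per unit Sp
    nhgb_insulin_nodes: list[float] = field(default_factory=_default_nhgb_insulin_nodes)
    nhgb_glucose_nodes: list[float] = field(default_factory=_default_nhgb_glucose_nodes)
    nhgb_values: list[list[float]] = field(default_factory=_default_nhgb_values)
    bg_floor_mmol_per_l: float = 0.5

    def __post_init__(self) -> None:
        for name in ("vg_l_per_kg", "vi_l_per_kg", "k_insulin_elim_per_h",
                     "k_active_transfer_per_h", "km_mmol_per_l", "carb_mmol_per_g",
                     "gut_absorption_per_h", "emptying_vmax_mmol_per_h",
                     "emptying_ramp_h", "util_base_mmol_per_h"):
            if not getattr(self, name) > 0:
                raise ModelError(f"{name} must be > 0")
        if self.util_insulin_slope < 0:
            raise ModelError("util_insulin_slope must be >= 0")
        grid = np.asarray(self.nhgb_values, dtype=float)
        xs = np.asarray(self.nhgb_insulin_nodes, dtype=float)
        gs = np.asarray(self.nhgb_glucose_nodes, dtype=float)
        if grid.shape != (len(xs), len(gs)):
            raise ModelError("NHGB grid shape does not match its node axes")
        if np.any(np.diff(xs) <= 0) or np.any(np.diff(gs) <= 0):
            raise ModelError("NHGB node axes must be strictly increasing")
        if np.any(np.diff(grid, axis=0) > 1e-12):
            raise ModelError("NHGB grid must be non-increasing along the insulin axis")
        if np.any(np.diff(grid, axis=1) > 1e-12):
            raise ModelError("NHGB grid must be non-increasing along the glucose axis")
        self._nhgb_interp = RegularGridInterpolator(
            (xs, gs), grid, method="linear", bounds_error=True)
        self._nhgb_xs = xs
        self._nhgb_gs = gs


class PresetParameter(str, Enum):
    RTG = "RTG"
    CCR = "CCR"
    HEPATIC_SENSITIVITY = "hepatic_sensitivity"
    PERIPHERAL_SENSITIVITY = "peripheral_sensitivity"


class PresetCategory(str, Enum):
    LOW_REDUCED = "low_reduced"
    NORMAL = "normal"
    HIGH_INCREASED = "high_increased"


#: categorical physiology presets offered by the simulator
_PRESETS: dict[PresetParameter, dict[PresetCategory, float]] = {
    PresetParameter.RTG: {
        PresetCategory.LOW_REDUCED: 7.0,
        PresetCategory.NORMAL: 9.0,
        PresetCategory.HIGH_INCREASED: 11.0,
    },
    PresetParameter.CCR: {
        PresetCategory.LOW_REDUCED: 40.0,
        PresetCategory.NORMAL: 100.0,
        # no "increased" creatinine clearance preset is offered
    },
    PresetParameter.HEPATIC_SENSITIVITY: {
        PresetCategory.LOW_REDUCED: 0.2,
        PresetCategory.NORMAL: 0.5,
        PresetCategory.HIGH_INCREASED: 0.8,
    },
    PresetParameter.PERIPHERAL_SENSITIVITY: {
        PresetCategory.LOW_REDUCED: 0.2,
        PresetCategory.NORMAL: 0.5,
        PresetCategory.HIGH_INCREASED: 0.8,
    },
}


def preset_lookup(parameter: PresetParameter | str,
                  category: PresetCategory | str) -> float:
    """Numeric value of a categorical physiology preset.

    RTG in mmol/L, CCR in mL/min, sensitivities dimensionless.  There is no
    high/increased CCR preset; asking for it is an error.
    """
    parameter = PresetParameter(parameter)
    category = PresetCategory(category)
    try:
        return _PRESETS[parameter][category]
    except KeyError:
        raise ModelError(
            f"no preset for {parameter.value} in category {category.value}") from None


@dataclass
class PatientParameters:
    """Per-patient physiology: weight plus the four preset-driven values."""

    weight_kg: float
    rtg_mmol_per_l: float = 9.0
    ccr_ml_per_min: float = 100.0
    hepatic_sensitivity: float = 0.5
    peripheral_sensitivity: float = 0.5

    def __post_init__(self) -> None:
        if not self.weight_kg > 0:
            raise ModelError("weight must be > 0")
        for name in ("rtg_mmol_per_l", "ccr_ml_per_min",
                     "hepatic_sensitivity", "peripheral_sensitivity"):
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be >= 0")

    @classmethod
    def from_categories(cls, weight_kg: float, rtg: str = "normal",
                        ccr: str = "normal", hepatic: str = "normal",
                        peripheral: str = "normal") -> "PatientParameters":
        return cls(
            weight_kg=weight_kg,
            rtg_mmol_per_l=preset_lookup(PresetParameter.RTG, rtg),
            ccr_ml_per_min=preset_lookup(PresetParameter.CCR, ccr),
            hepatic_sensitivity=preset_lookup(PresetParameter.HEPATIC_SENSITIVITY, hepatic),
            peripheral_sensitivity=preset_lookup(
                PresetParameter.PERIPHERAL_SENSITIVITY, peripheral),
        )

    @property
    def gfr_l_per_h(self) -> float:
        """Glomerular filtration rate estimated from creatinine clearance."""
        return self.ccr_ml_per_min * 60.0 / 1000.0


@dataclass
class DaySeries:
    """One 24-h series on the 15-min grid: 97 samples, point 96 = point 0."""

    values: np.ndarray
    units: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (GRID_POINTS,):
            raise ModelError(f"day series must have {GRID_POINTS} samples")
        if not np.all(np.isfinite(self.values)):
            raise ModelError("day series contains non-finite values")


TIME_GRID_MIN = np.arange(GRID_POINTS) * GRID_STEP_MIN
TIME_GRID_H = TIME_GRID_MIN / 60.0


# ---------------------------------------------------------------------------
# flux terms


def renal_excretion_rate(G: float, params: PatientParameters):
    """Urinary glucose loss (mmol/h): GFR * (G - RTG) above the threshold,
    zero at or below it (continuous at G = RTG)."""
    G = np.asarray(G, dtype=float)
    if np.any(G < 0):
        raise ModelError("blood glucose must be >= 0")
    rate = params.gfr_l_per_h * np.clip(G - params.rtg_mmol_per_l, 0.0, None)
    return float(rate) if rate.ndim == 0 else rate


def peripheral_utilization_rate(G, Ia, params: PatientParameters,
                                constants: ModelConstants):
    """Peripheral glucose uptake (mmol/h), saturable in G.

    (base + Sp * slope * Ia) * G/(Km+G): an insulin-independent term (brain,
    red cells) plus a term linear in active insulin Ia (mU/L).
    """
    G = np.asarray(G, dtype=float)
    Ia = np.asarray(Ia, dtype=float)
    if np.any(G < 0) or np.any(Ia < 0):
        raise ModelError("glucose and active insulin must be >= 0")
    capacity = (constants.util_base_mmol_per_h
                + params.peripheral_sensitivity * constants.util_insulin_slope * Ia)
    rate = capacity * G / (constants.km_mmol_per_l + G)
    return float(rate) if rate.ndim == 0 else rate


def net_hepatic_balance(G, Ia, params: PatientParameters,
                        constants: ModelConstants):
    """Net hepatic glucose balance (mmol/h, signed).

    Bilinear interpolation of the NHGB grid at (Sh * Ia, G); positive means
    hepatic production, negative hepatic uptake.  Arguments outside the grid
    hull are clamped to it (never extrapolated).
    """
    G = np.asarray(G, dtype=float)
    Ia = np.asarray(Ia, dtype=float)
    if np.any(G < 0) or np.any(Ia < 0):
        raise ModelError("glucose and active insulin must be >= 0")
    x = np.clip(params.hepatic_sensitivity * Ia,
                constants._nhgb_xs[0], constants._nhgb_xs[-1])
    g = np.clip(G, constants._nhgb_gs[0], constants._nhgb_gs[-1])
    pts = np.stack(np.broadcast_arrays(x, g), axis=-1)
    out = constants._nhgb_interp(pts)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# insulin day profile


def _snap_to_grid(time_min: float) -> int:
    idx = int(math.floor(time_min / GRID_STEP_MIN + 0.5)) % (GRID_POINTS - 1)
    if abs(time_min - idx * GRID_STEP_MIN) > 1e-9 and abs(
            time_min - (idx + GRID_POINTS - 1) * GRID_STEP_MIN) > 1e-9:
        logger.info("snapped time %.1f min to grid point %d (%d min)",
                    time_min, idx, idx * GRID_STEP_MIN)
    return idx


def _resolve_components(prep: InsulinPreparation, dose: float,
                        ) -> list[tuple[AbsorptionClass, float]]:
    if prep.category is InsulinCategory.BIPHASIC:
        short, inter = biphasic_split(dose, prep)
        return [(AbsorptionClass.ACTRAPID_LIKE, short),
                (prep.intermediate_component_class, inter)]
    return [(prep.absorption_class, dose)]


def insulin_day_profiles(injections: Sequence[tuple[float, float, InsulinPreparation]],
                         tables: Mapping[str, AbsorptionTable],
                         weight_kg: float,
                         constants: ModelConstants,
                         ) -> tuple[DaySeries, DaySeries]:
    """Periodic 24-h plasma and active insulin (mU/L) for a daily regimen.

    Each injection is (time in minutes since midnight, dose IU, preparation).
    Table rows already encode the steady-state daily repetition of one
    injection, so superposition is a circular shift to the injection time and
    a sum; the result is scaled by 1/(Vi * weight) into concentration.
    At most four injections of any one preparation are allowed.
    """
    per_prep: dict[str, int] = {}
    plasma = np.zeros(GRID_POINTS - 1)
    active = np.zeros(GRID_POINTS - 1)
    for time_min, dose, prep in injections:
        if not 0 <= time_min < MINUTES_PER_DAY:
            raise ModelError(f"injection time {time_min} min outside [0, 24 h)")
        per_prep[prep.name] = per_prep.get(prep.name, 0) + 1
        if per_prep[prep.name] > 4:
            raise ModelError(
                f"more than 4 daily injections of {prep.name} (limit is 4 per preparation)")
        for cls, component_dose in _resolve_components(prep, dose):
            if component_dose < 0 or component_dose > MAX_DOSE_IU:
                raise ModelError(
                    f"dose {component_dose} IU outside [0, {MAX_DOSE_IU}] after splitting")
            stem = CLASS_FILE_STEM[cls]
            shift = _snap_to_grid(time_min)
            plasma += np.roll(tables[f"{stem}_pa"].row(component_dose)[:-1], shift)
            active += np.roll(tables[f"{stem}_act"].row(component_dose)[:-1], shift)
    scale = 1000.0 / (constants.vi_l_per_kg * weight_kg)  # IU -> mU, per litre
    plasma_full = np.concatenate([plasma, plasma[:1]]) * scale
    active_full = np.concatenate([active, active[:1]]) * scale
    return DaySeries(plasma_full, "mU/L"), DaySeries(active_full, "mU/L")


def meal_day_profile(meals: Sequence[tuple[float, float]],
                     tables: Mapping[str, AbsorptionTable]) -> DaySeries:
    """Periodic 24-h gut glucose appearance (mmol/h) for up to six meals."""
    if len(meals) > 6:
        raise ModelError("more than 6 meals (limit is 6 per day)")
    total = np.zeros(GRID_POINTS - 1)
    for time_min, grams in meals:
        if not 0 <= time_min < MINUTES_PER_DAY:
            raise ModelError(f"meal time {time_min} min outside [0, 24 h)")
        shift = _snap_to_grid(time_min)
        total += np.roll(tables["CAR"].row(grams)[:-1], shift)
    return DaySeries(np.concatenate([total, total[:1]]), "mmol/h")


# ---------------------------------------------------------------------------
# Euler integration


def glucose_step(G: float, fluxes: tuple[float, float, float, float],
                 params: PatientParameters, constants: ModelConstants,
                 dt: float = 15.0) -> float:
    """One Euler step of the glucose balance.

    fluxes = (gut_in, nhgb, peripheral, renal) in mmol/h; dt in minutes.
    The result is floored at the configured minimum glucose.
    """
    gut_in, nhgb, peripheral, renal = fluxes
    if not all(np.isfinite(f) for f in fluxes):
        raise ModelError(f"non-finite flux in {fluxes}")
    net = gut_in + nhgb - peripheral - renal
    g_new = G + (dt / 60.0) * net / (constants.vg_l_per_kg * params.weight_kg)
    if g_new < constants.bg_floor_mmol_per_l:
        logger.warning("blood glucose clamped at the %.1f mmol/L floor",
                       constants.bg_floor_mmol_per_l)
        return constants.bg_floor_mmol_per_l
    return g_new


@dataclass
class DayResult:
    """One converged 24-h simulation: BG, insulin, fluxes and HbA1c."""

    bg: DaySeries                 # mmol/L
    plasma_insulin: DaySeries     # mU/L
    active_insulin: DaySeries | None  # mU/L; None for runs re-read from disk
    gut_absorption: DaySeries     # mmol/h
    renal_excretion: DaySeries    # mmol/h
    peripheral_utilization: DaySeries  # mmol/h
    nhgb: DaySeries               # mmol/h, signed
    mean_bg_mmol: float
    hba1c_percent: float
    iterations: int


def _periodic_upsample(series: np.ndarray, factor: int) -> np.ndarray:
    """Linearly interpolate a periodic 97-point series onto a finer grid."""
    if factor == 1:
        return series
    coarse = np.arange(GRID_POINTS) * GRID_STEP_MIN
    fine = np.arange((GRID_POINTS - 1) * factor + 1) * (GRID_STEP_MIN / factor)
    return np.interp(fine, coarse, series)


def simulate_day(scenario: "CaseScenario", params: PatientParameters,
                 tables: Mapping[str, AbsorptionTable],
                 constants: ModelConstants,
                 dt: float = 15.0,
                 hba1c_model: str = "classic",
                 tol: float = 0.01, max_iterations: int = 50) -> DayResult:
    """Integrate the model to its 24-h periodic steady state.

    The same daily meals and injections repeat; starting from 7.0 mmol/L the
    day is Euler-integrated (step ``dt`` minutes) again and again, each day
    starting where the last ended, until the maximum pointwise change between
    consecutive days is below ``tol`` mmol/L.  Output series are sampled on
    the 15-minute grid regardless of ``dt``.
    """
    from .scenario import CaseScenario  # local import to avoid a cycle
    from .profiles import get_preparation

    if dt <= 0 or GRID_STEP_MIN % dt:
        raise ModelError("dt must be a positive divisor of 15 minutes")
    factor = int(round(GRID_STEP_MIN / dt))

    injections = [
        (inj_time, dose, get_preparation(slot.preparation))
        for slot in scenario.insulin_slots
        for inj_time, dose in slot.injections
    ]
    plasma, active = insulin_day_profiles(injections, tables, params.weight_kg, constants)
    gut = meal_day_profile([(m.time_min, m.grams) for m in scenario.meals], tables)

    active_fine = _periodic_upsample(active.values, factor)
    gut_fine = _periodic_upsample(gut.values, factor)
    n = len(gut_fine) - 1  # steps per day

    dt_h = dt / 60.0
    vg = constants.vg_l_per_kg * params.weight_kg
    floor = constants.bg_floor_mmol_per_l

    # NHGB is bilinear in (Sh*Ia, G) and Ia is known per step, so interpolate
    # the insulin axis once; each Euler step then only interpolates over G.
    xs, gs = constants._nhgb_xs, constants._nhgb_gs
    grid = np.asarray(constants.nhgb_values, dtype=float)
    x_t = np.clip(params.hepatic_sensitivity * active_fine, xs[0], xs[-1])
    nhgb_of_g = np.column_stack(
        [np.interp(x_t, xs, grid[:, j]) for j in range(len(gs))])
    g_lo, g_hi = gs[0], gs[-1]
    km = constants.km_mmol_per_l
    capacity = (constants.util_base_mmol_per_h
                + params.peripheral_sensitivity
                * constants.util_insulin_slope * active_fine)
    gfr = params.gfr_l_per_h
    rtg = params.rtg_mmol_per_l

    prev_day = np.full(n + 1, 7.0)
    converged_at = None
    for iteration in range(1, max_iterations + 1):
        g_new = np.empty(n + 1)
        g_new[0] = prev_day[-1] if iteration > 1 else 7.0
        for i in range(n):
            gi = g_new[i]
            nhgb = np.interp(min(max(gi, g_lo), g_hi), gs, nhgb_of_g[i])
            peri = capacity[i] * gi / (km + gi)
            renal = gfr * (gi - rtg) if gi > rtg else 0.0
            net = gut_fine[i] + nhgb - peri - renal
            nxt = gi + dt_h * net / vg
            g_new[i + 1] = floor if nxt < floor else nxt
        residual = float(np.max(np.abs(g_new - prev_day)))
        prev_day = g_new
        if residual < tol:
            converged_at = iteration
            break
    if converged_at is None:
        raise ConvergenceError(
            f"no periodic steady state within {max_iterations} day iterations "
            f"(residual {residual:.4g} mmol/L)")

    g_final = prev_day
    nhgb_s = net_hepatic_balance(g_final, active_fine, params, constants)
    peri_s = peripheral_utilization_rate(g_final, active_fine, params, constants)
    renal_s = renal_excretion_rate(g_final, params)

    sl = slice(None, None, factor)
    bg = DaySeries(g_final[sl], "mmol/L")
    result_mean = mean_bg(bg)
    return DayResult(
        bg=bg,
        plasma_insulin=plasma,
        active_insulin=active,
        gut_absorption=gut,
        renal_excretion=DaySeries(renal_s[sl], "mmol/h"),
        peripheral_utilization=DaySeries(peri_s[sl], "mmol/h"),
        nhgb=DaySeries(nhgb_s[sl], "mmol/h"),
        mean_bg_mmol=result_mean,
        hba1c_percent=hba1c_estimate(result_mean * MGDL_PER_MMOL, hba1c_model),
        iterations=converged_at,
    )


# ---------------------------------------------------------------------------
# summary statistics


def mean_bg(series: DaySeries | np.ndarray) -> float:
    """Time-weighted daily mean of a periodic day series.

    The periodic trapezoid rule over 96 equal intervals reduces to the
    arithmetic mean of the first 96 samples (point 96 repeats point 0).
    """
    values = series.values if isinstance(series, DaySeries) else np.asarray(series)
    if values.shape != (GRID_POINTS,):
        raise ModelError(f"day series must have {GRID_POINTS} samples")
    return float(np.mean(values[: GRID_POINTS - 1]))


#: HbA1c (%) as a linear function of mean blood glucose (mg/dL)
HBA1C_MODELS = {
    "classic": lambda m: (m + 86.0) / 33.3,
    "eag": lambda m: (m + 46.7) / 28.7,   # inverse of eAG = 28.7*A1c - 46.7
}


def hba1c_estimate(mean_bg_mgdl: float, model: str = "classic") -> float:
    """Glycosylated haemoglobin (%) predicted from mean blood glucose (mg/dL).

    Strictly increasing linear regression; the default maps 200 mg/dL to
    about 8.6%.
    """
    if not mean_bg_mgdl > 0:
        raise ModelError(f"mean blood glucose must be > 0, got {mean_bg_mgdl}")
    try:
        return HBA1C_MODELS[model](mean_bg_mgdl)
    except KeyError:
        raise ModelError(f"unknown HbA1c model {model!r}") from None
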