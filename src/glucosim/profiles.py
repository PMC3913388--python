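"""Subcutaneous insulin and carbohydrate absorption profiles.

The simulator never integrates absorption kinetics at run time.  Instead it
precomputes, for every whole-unit insulin dose (0-40 IU) and every whole gram
of meal carbohydrate (0-80 g), the periodic 24-hour response to a daily
repeated input, and stores the results in nine whitespace-separated ASCII
lookup tables:

    Actrapid_act  Actrapid_pa  NPH_act  NPH_pa  Lente_act  Lente_pa
    UltraLente_act  UltraLente_pa  CAR

``_pa`` files hold the plasma-compartment insulin response, ``_act`` files
the effect-compartment ("active") insulin that actually drives the glucose
fluxes, and ``CAR`` holds gut glucose appearance rates after a meal.

The subcutaneous absorption model is the sigmoid-fraction family: the
cumulative fraction of a dose D absorbed by time t is

    F(t) = t^s / (T50(D)^s + t^s),        T50(D) = a*D + b

with a dose-dependent half-absorption time T50.  Because T50 grows with the
dose, kinetics are nonlinear in D, which is why the tables are indexed by
dose rather than scaled from a unit response.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .model import ModelConstants

__all__ = [
    "AbsorptionClass",
    "InsulinCategory",
    "InsulinPreparation",
    "AbsorptionClassParams",
    "AbsorptionTable",
    "ProfileFileSet",
    "PROFILE_FILE_NAMES",
    "GRID_STEP_MIN",
    "GRID_POINTS",
    "MAX_DOSE_IU",
    "MAX_GRAMS",
    "absorption_fraction",
    "absorption_rate",
    "single_injection_response",
    "build_insulin_tables",
    "gastric_emptying_profile",
    "build_carb_table",
    "build_all_tables",
    "biphasic_split",
    "load_registry",
    "get_preparation",
    "write_profile_files",
    "read_profile_files",
]

GRID_STEP_MIN = 15
GRID_POINTS = 97            # 0..24 h inclusive at 15-min steps
MAX_DOSE_IU = 40
MAX_GRAMS = 80

#: internal precompute horizon (hours) before folding onto the periodic day.
#: Long enough that the slowest class (UltraLente-like, T50 up to ~18 h)
#: leaves < 0.5% of its dose unabsorbed at truncation.
PRECOMPUTE_HORIZON_H = 144.0
PRECOMPUTE_DT_MIN = 1.0


class AbsorptionClass(str, Enum):
    """Absorption-speed class an insulin brand maps onto."""

    ACTRAPID_LIKE = "ACTRAPID_LIKE"
    NPH_LIKE = "NPH_LIKE"
    LENTE_LIKE = "LENTE_LIKE"
    ULTRALENTE_LIKE = "ULTRALENTE_LIKE"


class InsulinCategory(str, Enum):
    SHORT = "short"
    INTERMEDIATE = "intermediate"
    LONG = "long"
    BIPHASIC = "biphasic"


#: class -> base name of its pair of profile files
CLASS_FILE_STEM = {
    AbsorptionClass.ACTRAPID_LIKE: "Actrapid",
    AbsorptionClass.NPH_LIKE: "NPH",
    AbsorptionClass.LENTE_LIKE: "Lente",
    AbsorptionClass.ULTRALENTE_LIKE: "UltraLente",
}

PROFILE_FILE_NAMES = (
    "Actrapid_act", "Actrapid_pa",
    "NPH_act", "NPH_pa",
    "Lente_act", "Lente_pa",
    "UltraLente_act", "UltraLente_pa",
    "CAR",
)


class ProfileError(ValueError):
    """Base error for absorption-profile problems."""


class ProfileFileSetError(ProfileError):
    """Missing/extra/malformed member of the nine-file set."""


@dataclass(frozen=True)
class InsulinPreparation:
    """A named insulin brand and how it absorbs.

    Non-biphasic brands carry an ``absorption_class``; biphasic (premixed)
    brands instead carry the short-acting percentage and the class of their
    intermediate component, and are simulated as two separate injections.
    """

    name: str
    category: InsulinCategory
    absorption_class: AbsorptionClass | None = None
    percent_short: int | None = None
    intermediate_component_class: AbsorptionClass | None = None

    def __post_init__(self) -> None:
        if self.category is InsulinCategory.BIPHASIC:
            if self.absorption_class is not None:
                raise ProfileError(
                    f"{self.name}: biphasic preparation cannot carry an absorption class")
            if self.percent_short is None or not (1 <= self.percent_short <= 99):
                raise ProfileError(
                    f"{self.name}: biphasic preparation needs percent_short in 1..99")
            if self.intermediate_component_class not in (
                    AbsorptionClass.NPH_LIKE, AbsorptionClass.LENTE_LIKE):
                raise ProfileError(
                    f"{self.name}: biphasic intermediate component must be NPH- or Lente-like")
        else:
            if self.absorption_class is None:
                raise ProfileError(f"{self.name}: absorption class required")
            if self.percent_short is not None or self.intermediate_component_class is not None:
                raise ProfileError(
                    f"{self.name}: percent split is only valid for biphasic preparations")


@dataclass(frozen=True)
class AbsorptionClassParams:
    """Sigmoid absorption parameters for one class.

    shape_s          dimensionless sigmoid exponent (> 1)
    t50_slope_a      hours of extra half-absorption time per IU (>= 0)
    t50_intercept_b  half-absorption time of a vanishing dose, hours (> 0)
    """

    class_id: AbsorptionClass
    shape_s: float
    t50_slope_a: float
    t50_intercept_b: float

    def __post_init__(self) -> None:
        if not self.shape_s > 1:
            raise ProfileError(f"{self.class_id}: shape_s must be > 1")
        if self.t50_slope_a < 0:
            raise ProfileError(f"{self.class_id}: t50_slope_a must be >= 0")
        if not self.t50_intercept_b > 0:
            raise ProfileError(f"{self.class_id}: t50_intercept_b must be > 0")

    def t50(self, dose: float) -> float:
        """Half-absorption time, hours, for a given dose (IU)."""
        return self.t50_slope_a * dose + self.t50_intercept_b


class TableKind(str, Enum):
    INSULIN_PLASMA = "insulin_plasma"
    INSULIN_ACTIVE = "insulin_active"
    CARBOHYDRATE = "carbohydrate"


@dataclass
class AbsorptionTable:
    """Dose- (or grams-) indexed lookup table on the 15-min day grid.

    Insulin tables are 41 rows (0-40 IU) x 97 columns; the carbohydrate
    table is 81 rows (0-80 g) x 97 columns.  Row 0 is identically zero.
    Insulin values are IU of insulin in the compartment per daily repeated
    injection (distribution volume applied at simulation time); carbohydrate
    values are gut glucose appearance in mmol/h.
    """

    kind: TableKind
    values: np.ndarray
    class_id: AbsorptionClass | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        rows = MAX_GRAMS + 1 if self.kind is TableKind.CARBOHYDRATE else MAX_DOSE_IU + 1
        if self.values.shape != (rows, GRID_POINTS):
            raise ProfileError(
                f"{self.kind.value} table must be {rows}x{GRID_POINTS}, "
                f"got {self.values.shape}")
        if self.kind is not TableKind.CARBOHYDRATE and self.class_id is None:
            raise ProfileError("insulin tables need a class_id")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ProfileError(f"{self.kind.value} table has negative or non-finite values")
        if np.any(self.values[0] != 0.0):
            raise ProfileError(f"{self.kind.value} table row 0 must be all zeros")

    @property
    def row_index_unit(self) -> str:
        return "g" if self.kind is TableKind.CARBOHYDRATE else "IU"

    def row(self, offset: float) -> np.ndarray:
        """Look up the row for a dose/grams value, rounded to the nearest
        integer offset (no interpolation between rows)."""
        idx = int(math.floor(offset + 0.5))
        hi = self.values.shape[0] - 1
        unit = self.row_index_unit
        if offset < 0:
            raise ProfileError(f"negative {unit} offset: {offset}")
        if idx > hi:
            raise ProfileError(f"{offset} {unit} exceeds the {hi} {unit} table bound")
        return self.values[idx]


@dataclass
class ProfileFileSet:
    """Handle onto a directory holding the nine named profile files."""

    directory: Path
    members: tuple[str, ...] = PROFILE_FILE_NAMES

    def paths(self) -> dict[str, Path]:
        return {name: self.directory / name for name in self.members}


# ---------------------------------------------------------------------------
# absorption kinetics


def _check_dose(dose: float) -> None:
    if dose <= 0 or dose > MAX_DOSE_IU:
        raise ProfileError(f"dose must be in (0, {MAX_DOSE_IU}] IU, got {dose}")


def absorption_fraction(t: float, dose: float, params: AbsorptionClassParams) -> float:
    """Cumulative fraction of a subcutaneous dose absorbed t hours after
    injection: t^s / (T50(dose)^s + t^s)."""
    if t < 0:
        raise ProfileError(f"time since injection must be >= 0, got {t}")
    _check_dose(dose)
    t50 = params.t50(dose)
    s = params.shape_s
    ts = t ** s
    return ts / (t50 ** s + ts)


def absorption_rate(t, dose: float, params: AbsorptionClassParams):
    """Absorption rate (IU/h) at time(s) t: dose * dF/dt (vectorised)."""
    _check_dose(dose)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ProfileError("time since injection must be >= 0")
    s = params.shape_s
    t50s = params.t50(dose) ** s
    with np.errstate(invalid="ignore"):
        num = dose * s * t50s * np.where(t > 0, t, 1.0) ** (s - 1.0)
    rate = np.where(t > 0, num / (t50s + t ** s) ** 2, 0.0)
    return rate


def _integrate_compartments(rates: np.ndarray, ke: float, k_act: float,
                            dt_h: float) -> tuple[np.ndarray, np.ndarray]:
    """Euler-integrate plasma and effect compartments driven by absorption.

    ``rates`` has shape (n_inputs, n_steps); returns arrays of the same
    shape holding compartment contents (IU) at each step.
    """
    n, steps = rates.shape
    plasma = np.zeros((n, steps))
    active = np.zeros((n, steps))
    for i in range(1, steps):
        p = plasma[:, i - 1]
        a = active[:, i - 1]
        plasma[:, i] = p + dt_h * (rates[:, i - 1] - ke * p)
        active[:, i] = a + dt_h * k_act * (p - a)
    return plasma, active


def single_injection_response(dose: float, class_params: AbsorptionClassParams,
                              constants: "ModelConstants",
                              horizon: float = PRECOMPUTE_HORIZON_H,
                              dt: float = PRECOMPUTE_DT_MIN,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Plasma- and effect-compartment insulin (IU) after one injection.

    Returns the two series sampled on the 15-minute grid over ``horizon``
    hours.  The plasma compartment sees the absorption rate of the sigmoid
    model and first-order elimination ``ke``; the active compartment is a
    first-order lag behind plasma.  Values are per unit distribution volume
    (patient weight and Vi are applied at simulation time).
    """
    if horizon < 24:
        raise ProfileError("horizon must be at least 24 h")
    if 60 % dt and dt % 1:
        raise ProfileError("dt must divide 60 minutes")
    dt_h = dt / 60.0
    steps = int(round(horizon / dt_h)) + 1
    t = np.arange(steps) * dt_h
    if dose == 0:
        n15 = int(round(horizon * 60 / GRID_STEP_MIN)) + 1
        zero = np.zeros(n15)
        return zero, zero.copy()
    _check_dose(dose)
    rates = absorption_rate(t, dose, class_params)[None, :]
    plasma, active = _integrate_compartments(
        rates, constants.k_insulin_elim_per_h, constants.k_active_transfer_per_h, dt_h)
    if not (np.all(np.isfinite(plasma)) and np.all(np.isfinite(active))):
        raise ProfileError(
            f"non-finite insulin response for {class_params.class_id} at {dose} IU")
    stride = int(round(GRID_STEP_MIN / dt))
    return plasma[0, ::stride], active[0, ::stride]


def _fold_to_day(series: np.ndarray) -> np.ndarray:
    """Fold a long 15-min-grid response onto the periodic 24-h grid.

    The folded value at grid point j is the steady-state level seen at clock
    offset j when the same input is repeated every day: sum over day k of
    series[j + 96k].  Point 96 duplicates point 0 (periodic closure).
    """
    per_day = GRID_POINTS - 1
    n_days = (len(series) - 1) // per_day
    trimmed = series[: n_days * per_day]
    folded = trimmed.reshape(n_days, per_day).sum(axis=0)
    return np.concatenate([folded, folded[:1]])


def build_insulin_tables(class_params: AbsorptionClassParams,
                         constants: "ModelConstants",
                         ) -> tuple[AbsorptionTable, AbsorptionTable]:
    """Build the (plasma, active) dose-indexed tables for one class.

    Row d (0..40) is the periodic-day fold of the single-injection response
    at d IU.  Computed for all doses in one vectorised Euler pass.
    """
    dt_h = PRECOMPUTE_DT_MIN / 60.0
    steps = int(round(PRECOMPUTE_HORIZON_H / dt_h)) + 1
    t = np.arange(steps) * dt_h
    doses = np.arange(1, MAX_DOSE_IU + 1)
    rates = np.vstack([absorption_rate(t, float(d), class_params) for d in doses])
    plasma, active = _integrate_compartments(
        rates, constants.k_insulin_elim_per_h, constants.k_active_transfer_per_h, dt_h)
    stride = int(round(GRID_STEP_MIN / PRECOMPUTE_DT_MIN))
    pa = np.zeros((MAX_DOSE_IU + 1, GRID_POINTS))
    act = np.zeros((MAX_DOSE_IU + 1, GRID_POINTS))
    for i, _ in enumerate(doses, start=1):
        pa[i] = _fold_to_day(plasma[i - 1, ::stride])
        act[i] = _fold_to_day(active[i - 1, ::stride])
    return (AbsorptionTable(TableKind.INSULIN_PLASMA, pa, class_params.class_id),
            AbsorptionTable(TableKind.INSULIN_ACTIVE, act, class_params.class_id))


# ---------------------------------------------------------------------------
# carbohydrate absorption


def _gastric_emptying_rate(t: np.ndarray, ch_mmol: float,
                           constants: "ModelConstants") -> np.ndarray:
    """Trapezoidal gastric emptying rate (mmol/h) for a load of ch_mmol.

    Large loads empty as a trapezoid: ramp up over the ascent time, plateau
    at Vmax, ramp down.  Loads below the critical load Vmax*(Tasc+Tdes)/2
    empty as a triangle with the same ramp times and a reduced peak.
    """
    vmax = constants.emptying_vmax_mmol_per_h
    ramp = constants.emptying_ramp_h
    critical = vmax * ramp  # = vmax*(Tasc+Tdes)/2 with Tasc = Tdes = ramp
    rate = np.zeros_like(t)
    if ch_mmol <= 0:
        return rate
    if ch_mmol > critical:
        plateau = (ch_mmol - critical) / vmax
        up = t < ramp
        flat = (t >= ramp) & (t < ramp + plateau)
        down = (t >= ramp + plateau) & (t < 2 * ramp + plateau)
        rate[up] = vmax * t[up] / ramp
        rate[flat] = vmax
        rate[down] = vmax * (1 - (t[down] - ramp - plateau) / ramp)
    else:
        peak = ch_mmol / ramp  # triangle area = peak * ramp = ch_mmol
        up = t < ramp
        down = (t >= ramp) & (t < 2 * ramp)
        rate[up] = peak * t[up] / ramp
        rate[down] = peak * (1 - (t[down] - ramp) / ramp)
    return rate


def gastric_emptying_profile(grams: float, constants: "ModelConstants") -> np.ndarray:
    """Gut glucose appearance (mmol/h) on the periodic 24-h 15-min grid for a
    meal of ``grams`` carbohydrate.

    The stomach empties the load as a trapezoid/triangle; the gut compartment
    absorbs it first-order, and the absorption flux is what appears in blood.
    The day-integral equals grams x 5.551 mmol/g (up to truncation < 1%).
    """
    if grams < 0:
        raise ProfileError(f"grams must be >= 0, got {grams}")
    if grams > MAX_GRAMS:
        raise ProfileError(f"{grams} g exceeds the {MAX_GRAMS} g table bound")
    dt_h = PRECOMPUTE_DT_MIN / 60.0
    steps = int(round(PRECOMPUTE_HORIZON_H / dt_h)) + 1
    t = np.arange(steps) * dt_h
    ch = grams * constants.carb_mmol_per_g
    emptying = _gastric_emptying_rate(t, ch, constants)
    k = constants.gut_absorption_per_h
    gut = np.zeros(steps)
    for i in range(1, steps):
        gut[i] = gut[i - 1] + dt_h * (emptying[i - 1] - k * gut[i - 1])
    appearance = k * gut
    stride = int(round(GRID_STEP_MIN / PRECOMPUTE_DT_MIN))
    sampled = appearance[::stride]
    # fold conserves the integral; carb tails are short but folding keeps
    # the same periodic-day semantics as the insulin tables
    per_day = GRID_POINTS - 1
    n_days = (len(sampled) - 1) // per_day
    folded = sampled[: n_days * per_day].reshape(n_days, per_day).sum(axis=0)
    return np.concatenate([folded, folded[:1]])


def build_carb_table(constants: "ModelConstants") -> AbsorptionTable:
    """81-row grams-indexed gut appearance table (row g = profile for g grams)."""
    values = np.zeros((MAX_GRAMS + 1, GRID_POINTS))
    for g in range(1, MAX_GRAMS + 1):
        values[g] = gastric_emptying_profile(g, constants)
    return AbsorptionTable(TableKind.CARBOHYDRATE, values)


def build_all_tables(class_params: Mapping[AbsorptionClass, AbsorptionClassParams],
                     constants: "ModelConstants") -> dict[str, AbsorptionTable]:
    """Build the full nine-member table set keyed by profile file name."""
    tables: dict[str, AbsorptionTable] = {}
    for cls, stem in CLASS_FILE_STEM.items():
        pa, act = build_insulin_tables(class_params[cls], constants)
        tables[f"{stem}_pa"] = pa
        tables[f"{stem}_act"] = act
    tables["CAR"] = build_carb_table(constants)
    return tables


# ---------------------------------------------------------------------------
# biphasic preparations


def biphasic_split(dose: float, prep: InsulinPreparation) -> tuple[float, float]:
    """Split a premixed dose into its (short, intermediate) components.

    E.g. 10 IU of a 30/70 premix gives (3, 7).  The components are then
    simulated as two separate injections at the same time.
    """
    if prep.category is not InsulinCategory.BIPHASIC:
        raise ProfileError(f"{prep.name} is not a biphasic preparation")
    if dose < 0:
        raise ProfileError(f"dose must be >= 0, got {dose}")
    short = dose * prep.percent_short / 100.0
    return short, dose - short


# ---------------------------------------------------------------------------
# preparation registry

_REGISTRY_CACHE: dict[str, InsulinPreparation] | None = None


def load_registry(path: Path | None = None) -> dict[str, InsulinPreparation]:
    """Load the brand registry (name -> preparation) from its TSV config.

    The packaged registry carries 10 short-, 19 intermediate-, 4 long-acting
    and 18 biphasic named entries.
    """
    global _REGISTRY_CACHE
    if path is None and _REGISTRY_CACHE is not None:
        return dict(_REGISTRY_CACHE)
    if path is None:
        text = (importlib.resources.files("glucosim.data")
                / "insulin_registry.tsv").read_text()
    else:
        text = Path(path).read_text()
    registry: dict[str, InsulinPreparation] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ProfileError(f"registry line {lineno}: expected 3 tab-separated fields")
        name, category, detail = parts
        cat = InsulinCategory(category)
        if cat is InsulinCategory.BIPHASIC:
            pct, comp = detail.split("/")
            prep = InsulinPreparation(
                name, cat, percent_short=int(pct),
                intermediate_component_class=AbsorptionClass(comp))
        else:
            prep = InsulinPreparation(name, cat, absorption_class=AbsorptionClass(detail))
        if name in registry:
            raise ProfileError(f"registry line {lineno}: duplicate brand {name!r}")
        registry[name] = prep
    if path is None:
        _REGISTRY_CACHE = dict(registry)
    return registry


def get_preparation(name: str, registry: Mapping[str, InsulinPreparation] | None = None,
                    ) -> InsulinPreparation:
    reg = registry if registry is not None else load_registry()
    try:
        return reg[name]
    except KeyError:
        raise ProfileError(f"unknown insulin preparation {name!r}") from None


# ---------------------------------------------------------------------------
# ASCII file round trip

_HEADER_FMT = "# kind={kind} class={cls} row_unit={unit} grid=0:1440:15 rows={rows}"


def write_profile_files(tables: Mapping[str, AbsorptionTable],
                        directory: Path | str) -> ProfileFileSet:
    """Write the nine-member table set as ASCII files into ``directory``."""
    missing = [n for n in PROFILE_FILE_NAMES if n not in tables]
    if missing:
        raise ProfileFileSetError(f"incomplete table set, missing: {', '.join(missing)}")
    extra = [n for n in tables if n not in PROFILE_FILE_NAMES]
    if extra:
        raise ProfileFileSetError(f"unexpected table names: {', '.join(extra)}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in PROFILE_FILE_NAMES:
        table = tables[name]
        header = _HEADER_FMT.format(
            kind=table.kind.value,
            cls=table.class_id.value if table.class_id else "-",
            unit=table.row_index_unit,
            rows=table.values.shape[0])
        lines = [header]
        for row in table.values:
            lines.append(" ".join(f"{v:.12g}" for v in row))
        (directory / name).write_text("\n".join(lines) + "\n")
    return ProfileFileSet(directory)


def read_profile_files(directory: Path | str) -> dict[str, AbsorptionTable]:
    """Read the nine-member table set back; inverse of write_profile_files."""
    directory = Path(directory)
    tables: dict[str, AbsorptionTable] = {}
    for name in PROFILE_FILE_NAMES:
        path = directory / name
        if not path.exists():
            raise ProfileFileSetError(f"profile file set incomplete: missing {name}")
        lines = path.read_text().splitlines()
        if not lines or not lines[0].startswith("# kind="):
            raise ProfileFileSetError(f"{name}: missing header line")
        fields = dict(tok.split("=", 1) for tok in lines[0][2:].split())
        kind = TableKind(fields["kind"])
        cls = None if fields["class"] == "-" else AbsorptionClass(fields["class"])
        rows = []
        for lineno, line in enumerate(lines[1:], start=2):
            vals = line.split()
            if len(vals) != GRID_POINTS:
                raise ProfileFileSetError(
                    f"{name} line {lineno}: expected {GRID_POINTS} values, got {len(vals)}")
            rows.append([float(v) for v in vals])
        tables[name] = AbsorptionTable(kind, np.array(rows), cls)
    return tables
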