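"""Run orchestration: options, unit conversion, run numbering, the two-run
comparison session, and export of the six per-run data files.

A session mimics the original web workflow: it holds at most the current
run and the immediately previous one, numbers runs from 1, and stamps a
per-session identifier into every exported filename so concurrent sessions
never collide.  Each completed run can be exported as six two-column ASCII
files (blood glucose, plasma insulin and the four glucose fluxes) at
15-minute resolution.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np

from .config import SimulatorConfig
from .model import (
    DayResult,
    MGDL_PER_MMOL,
    ModelError,
    PatientParameters,
    TIME_GRID_H,
    simulate_day,
)
from .scenario import CaseScenario, validate_scenario, ScenarioError

__all__ = [
    "BGUnits",
    "DisplayMode",
    "InsulinMode",
    "SimulatorOptions",
    "SimulationRun",
    "Session",
    "EngineError",
    "run_simulation",
    "convert_bg",
    "export_run",
    "comparison_payload",
    "ComparisonPayload",
    "EXPORT_SERIES",
]


class EngineError(ValueError):
    pass


class BGUnits(str, Enum):
    MMOL_PER_L = "mmol_per_L"
    MG_PER_DL = "mg_per_dL"

    @property
    def factor(self) -> float:
        """Multiplier from mmol/L into this unit (1 or 18)."""
        return MGDL_PER_MMOL if self is BGUnits.MG_PER_DL else 1.0


class DisplayMode(str, Enum):
    STANDARD = "standard"   # BG + plasma insulin panels
    ADVANCED = "advanced"   # plus the four flux panels


class InsulinMode(str, Enum):
    STANDARD = "standard"
    PREMIXED = "premixed"


#: default normoglycaemic band shown when bounds display is enabled unset
DEFAULT_BOUNDS_MMOL = (4.0, 10.0)


@dataclass(frozen=True)
class SimulatorOptions:
    bg_units: BGUnits = BGUnits.MMOL_PER_L
    display: DisplayMode = DisplayMode.STANDARD
    insulin_mode: InsulinMode = InsulinMode.STANDARD
    bounds: tuple[float, float] | None = None
    show_bounds: bool = False

    def __post_init__(self) -> None:
        if self.bounds is not None and not self.bounds[0] < self.bounds[1]:
            raise EngineError(
                f"lower bound must be below upper bound, got {self.bounds}")

    def effective_bounds(self) -> tuple[float, float] | None:
        """Bounds to draw (mmol/L), or None when display is off."""
        if not self.show_bounds:
            return None
        return self.bounds if self.bounds is not None else DEFAULT_BOUNDS_MMOL


@dataclass
class SimulationRun:
    """One completed 24-h simulation plus the context that produced it."""

    run_number: int
    scenario: CaseScenario
    result: DayResult
    options: SimulatorOptions

    @property
    def hba1c_percent(self) -> float:
        return self.result.hba1c_percent


def _new_session_id(rng: random.Random | None = None) -> str:
    rng = rng or random.SystemRandom()
    return f"{rng.randrange(10000, 100000):05d}"


@dataclass
class Session:
    """Holds at most two runs: the current one and the previous one.

    ``last_run_number`` lets a session restored from disk keep numbering
    even when the previous run's series are no longer available.
    """

    session_id: str = field(default_factory=_new_session_id)
    current: SimulationRun | None = None
    previous: SimulationRun | None = None
    last_run_number: int = 0

    @property
    def run_count(self) -> int:
        return (self.current is not None) + (self.previous is not None)


def run_simulation(scenario: CaseScenario, options: SimulatorOptions,
                   session: Session, config: SimulatorConfig,
                   ) -> tuple[SimulationRun, Session]:
    """Validate, simulate to steady state and push the run into the session.

    The new run gets number previous+1 (1 for a fresh session); the session
    afterwards retains only this run and the one before it.
    """
    problems = validate_scenario(scenario)
    if problems:
        raise ScenarioError("; ".join(problems))
    params = PatientParameters.from_categories(
        scenario.weight_kg, rtg=scenario.rtg, ccr=scenario.ccr,
        hepatic=scenario.hepatic, peripheral=scenario.peripheral)
    result = simulate_day(scenario, params, config.tables(), config.constants,
                          hba1c_model=config.hba1c_model)
    base = session.current.run_number if session.current else session.last_run_number
    run = SimulationRun(base + 1, scenario, result, options)
    session.previous = session.current
    session.current = run
    session.last_run_number = run.run_number
    return run, session


def convert_bg(value, from_units: BGUnits | str, to_units: BGUnits | str):
    """Convert a blood glucose value or series between mmol/L and mg/dL
    (18 mg/dL per mmol/L); same-unit conversion is the identity."""
    try:
        f, t = BGUnits(from_units), BGUnits(to_units)
    except ValueError as exc:
        raise EngineError(f"unknown blood glucose unit: {exc}") from None
    if f is t:
        return value
    arr = np.asarray(value, dtype=float)
    out = arr * (t.factor / f.factor)
    return float(out) if out.ndim == 0 else out


#: (filename stem, attribute on DayResult, unit label)
EXPORT_SERIES = (
    ("bg", "bg", "mmol/L"),
    ("insulin", "plasma_insulin", "mU/L"),
    ("absorption", "gut_absorption", "mmol/h"),
    ("renal", "renal_excretion", "mmol/h"),
    ("peripheral", "peripheral_utilization", "mmol/h"),
    ("nhgb", "nhgb", "mmol/h"),
)


def export_run(run: SimulationRun, directory: Path | str,
               session_id: str = "00000") -> list[Path]:
    """Write the six two-column (time h, value) ASCII data files for a run.

    Filenames carry the session id and run number; 97 data rows each.
    Blood glucose is written in the run's display units.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise EngineError(f"cannot create export directory {directory}: {exc}") from exc
    paths = []
    for stem, attr, units in EXPORT_SERIES:
        series = getattr(run.result, attr)
        values = series.values
        if stem == "bg":
            values = convert_bg(values, BGUnits.MMOL_PER_L, run.options.bg_units)
            units = "mg/dL" if run.options.bg_units is BGUnits.MG_PER_DL else "mmol/L"
        path = directory / f"{stem}_{session_id}_r{run.run_number}.dat"
        lines = [f"# time_h {stem} ({units})"]
        lines += [f"{t:.2f} {v:.6f}" for t, v in zip(TIME_GRID_H, values)]
        try:
            path.write_text("\n".join(lines) + "\n")
        except OSError as exc:
            raise EngineError(f"cannot write {path}: {exc}") from exc
        paths.append(path)
    return paths


def import_run(directory: Path | str, session_id: str, run_number: int,
               scenario: CaseScenario, options: SimulatorOptions,
               hba1c_model: str = "classic") -> SimulationRun:
    """Rebuild a run from its six exported data files (for overlays across
    separate invocations).  The effect-compartment series is not exported,
    so the rebuilt result carries None for it."""
    from .model import DaySeries, hba1c_estimate, mean_bg

    directory = Path(directory)
    series: dict[str, np.ndarray] = {}
    for stem, attr, _units in EXPORT_SERIES:
        path = directory / f"{stem}_{session_id}_r{run_number}.dat"
        if not path.exists():
            raise EngineError(f"exported data file missing: {path.name}")
        series[attr] = np.loadtxt(path, comments="#")[:, 1]
    bg_mmol = convert_bg(series["bg"], options.bg_units, BGUnits.MMOL_PER_L)
    mean = mean_bg(DaySeries(np.asarray(bg_mmol), "mmol/L"))
    result = DayResult(
        bg=DaySeries(np.asarray(bg_mmol), "mmol/L"),
        plasma_insulin=DaySeries(series["plasma_insulin"], "mU/L"),
        active_insulin=None,
        gut_absorption=DaySeries(series["gut_absorption"], "mmol/h"),
        renal_excretion=DaySeries(series["renal_excretion"], "mmol/h"),
        peripheral_utilization=DaySeries(series["peripheral_utilization"], "mmol/h"),
        nhgb=DaySeries(series["nhgb"], "mmol/h"),
        mean_bg_mmol=mean,
        hba1c_percent=hba1c_estimate(mean * MGDL_PER_MMOL, hba1c_model),
        iterations=0,
    )
    return SimulationRun(run_number, scenario, result, options)


@dataclass
class ComparisonPayload:
    """What the plotting layer needs to overlay current vs previous run."""

    current: SimulationRun
    previous: SimulationRun | None
    bounds_mmol: tuple[float, float] | None
    bg_units: BGUnits


def comparison_payload(session: Session) -> ComparisonPayload:
    """Overlay description for the session: current run highlighted, the
    previous run (if any) as the comparison series, plus bounds lines."""
    if session.current is None:
        raise EngineError("session holds no runs yet")
    options = session.current.options
    return ComparisonPayload(
        current=session.current,
        previous=session.previous,
        bounds_mmol=options.effective_bounds(),
        bg_units=options.bg_units,
    )
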