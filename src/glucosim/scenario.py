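"""Case scenarios: virtual patients, their ASCII file format, validation,
the 40 packaged cases and a seeded fixture generator.

A case scenario describes one virtual patient with insulin-dependent
diabetes: body weight, up to six meals (time and grams of carbohydrate), up
to two insulin preparations with up to four injections each, and the four
categorical physiology settings (renal glucose threshold, creatinine
clearance, hepatic and peripheral insulin sensitivity).

The on-disk format is line-oriented ``key: value`` ASCII (``.aida`` files),
one scenario per file, with repeated ``meal:`` and ``injection:`` lines.
Lines starting with ``#`` are comments and ignored.

The 40 packaged cases are synthetic reconstructions: the narrative details
published for cases 0001, 0010 and 0026 are honoured, the remainder are
authored afresh in the same style.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .profiles import MAX_DOSE_IU, MAX_GRAMS, load_registry

__all__ = [
    "Meal",
    "InsulinSlot",
    "CaseScenario",
    "ScenarioError",
    "ScenarioParseError",
    "parse_scenario",
    "write_scenario",
    "validate_scenario",
    "builtin_cases",
    "builtin_case",
    "random_scenario",
    "CATEGORY_TOKENS",
]

MINUTES_PER_DAY = 1440

#: tokens accepted in scenario files -> canonical preset category
CATEGORY_TOKENS = {
    "low": "low_reduced",
    "reduced": "low_reduced",
    "low_reduced": "low_reduced",
    "normal": "normal",
    "high": "high_increased",
    "increased": "high_increased",
    "high_increased": "high_increased",
}
_CATEGORY_OUT = {"low_reduced": "low", "normal": "normal", "high_increased": "high"}


class ScenarioError(ValueError):
    pass


class ScenarioParseError(ScenarioError):
    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass(frozen=True)
class Meal:
    time_min: float
    grams: float


@dataclass(frozen=True)
class InsulinSlot:
    preparation: str
    injections: tuple[tuple[float, float], ...]  # (time_min, dose IU)


@dataclass
class CaseScenario:
    id: str = "0000"
    name: str = ""
    description: str = ""
    weight_kg: float = 70.0
    meals: list[Meal] = field(default_factory=list)
    insulin_slots: list[InsulinSlot] = field(default_factory=list)
    rtg: str = "normal"
    ccr: str = "normal"
    hepatic: str = "normal"
    peripheral: str = "normal"

    def with_meal(self, time_min: float, grams: float) -> "CaseScenario":
        """Copy with one meal replaced (matched by time) or added."""
        meals = [m for m in self.meals if m.time_min != time_min]
        meals.append(Meal(time_min, grams))
        meals.sort(key=lambda m: m.time_min)
        return replace(self, meals=meals)

    def with_injection(self, preparation: str, time_min: float,
                       dose: float) -> "CaseScenario":
        """Copy with one injection of ``preparation`` at ``time_min`` set to
        ``dose`` (replacing any existing injection at that time)."""
        slots = []
        found = False
        for slot in self.insulin_slots:
            if slot.preparation == preparation:
                found = True
                inj = [(t, d) for t, d in slot.injections if t != time_min]
                inj.append((time_min, dose))
                inj.sort()
                slots.append(InsulinSlot(preparation, tuple(inj)))
            else:
                slots.append(slot)
        if not found:
            slots.append(InsulinSlot(preparation, ((time_min, dose),)))
        return replace(self, insulin_slots=slots)


# ---------------------------------------------------------------------------
# format


_TIME_RE = re.compile(r"^(\d{1,2}):(\d{2})$")


def _parse_time(token: str, lineno: int) -> float:
    m = _TIME_RE.match(token)
    if not m:
        raise ScenarioParseError(lineno, f"bad HH:MM time {token!r}")
    h, mi = int(m.group(1)), int(m.group(2))
    if h > 23 or mi > 59:
        raise ScenarioParseError(lineno, f"time {token!r} outside 00:00-23:59")
    return float(h * 60 + mi)


def _fmt_time(time_min: float) -> str:
    t = int(round(time_min))
    return f"{t // 60:02d}:{t % 60:02d}"


def _fmt_num(x: float) -> str:
    return f"{x:g}"


def parse_scenario(text: str) -> CaseScenario:
    """Parse the ``key: value`` scenario format; inverse of write_scenario.

    Omitted physiology categories default to normal.  Raises
    ScenarioParseError (with the line number) on malformed lines and
    ScenarioError on out-of-range fields.
    """
    sc = CaseScenario()
    current_slot: list | None = None

    def close_slot():
        nonlocal current_slot
        if current_slot is not None:
            sc.insulin_slots.append(InsulinSlot(current_slot[0], tuple(current_slot[1])))
            current_slot = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ScenarioParseError(lineno, f"expected 'key: value', got {line!r}")
        key, _, value = line.partition(":")
        key = key.strip().lower()
        value = value.strip()
        if key == "id":
            sc.id = value
        elif key == "name":
            sc.name = value
        elif key == "description":
            sc.description = value
        elif key == "weight":
            parts = value.split()
            if not parts:
                raise ScenarioParseError(lineno, "empty weight")
            try:
                w = float(parts[0])
            except ValueError:
                raise ScenarioParseError(lineno, f"bad weight {parts[0]!r}") from None
            unit = parts[1].lower() if len(parts) > 1 else "kg"
            if unit == "lb":
                w *= 0.45359237
            elif unit != "kg":
                raise ScenarioParseError(lineno, f"unknown weight unit {unit!r}")
            sc.weight_kg = w
        elif key == "meal":
            parts = value.split()
            if len(parts) != 2:
                raise ScenarioParseError(lineno, "meal needs 'HH:MM grams'")
            t = _parse_time(parts[0], lineno)
            try:
                grams = float(parts[1])
            except ValueError:
                raise ScenarioParseError(lineno, f"bad grams {parts[1]!r}") from None
            if len(sc.meals) >= 6:
                raise ScenarioError(
                    "more than 6 meal entries (the simulator offers 6 carbohydrate "
                    "entry points per day)")
            sc.meals.append(Meal(t, grams))
        elif key == "insulin":
            close_slot()
            if len(sc.insulin_slots) >= 2:
                raise ScenarioError("more than 2 insulin preparations (limit is 2)")
            current_slot = [value, []]
        elif key == "injection":
            if current_slot is None:
                raise ScenarioParseError(lineno, "injection before any 'insulin:' line")
            parts = value.split()
            if len(parts) != 2:
                raise ScenarioParseError(lineno, "injection needs 'HH:MM dose'")
            t = _parse_time(parts[0], lineno)
            try:
                dose = float(parts[1])
            except ValueError:
                raise ScenarioParseError(lineno, f"bad dose {parts[1]!r}") from None
            if len(current_slot[1]) >= 4:
                raise ScenarioError(
                    f"more than 4 injections of {current_slot[0]} "
                    "(up to four injections per day of each insulin type)")
            current_slot[1].append((t, dose))
        elif key in ("rtg", "ccr", "hepatic", "peripheral"):
            token = value.lower()
            if token not in CATEGORY_TOKENS:
                raise ScenarioParseError(lineno, f"unknown category token {value!r}")
            setattr(sc, key, CATEGORY_TOKENS[token])
        else:
            raise ScenarioParseError(lineno, f"unknown key {key!r}")
    close_slot()
    return sc


def write_scenario(sc: CaseScenario) -> str:
    """Serialise a scenario to its canonical ASCII form."""
    lines = [f"id: {sc.id}", f"name: {sc.name}"]
    if sc.description:
        lines.append(f"description: {sc.description}")
    lines.append(f"weight: {_fmt_num(sc.weight_kg)} kg")
    for m in sc.meals:
        lines.append(f"meal: {_fmt_time(m.time_min)} {_fmt_num(m.grams)}")
    for slot in sc.insulin_slots:
        lines.append(f"insulin: {slot.preparation}")
        for t, d in slot.injections:
            lines.append(f"injection: {_fmt_time(t)} {_fmt_num(d)}")
    for key in ("rtg", "ccr", "hepatic", "peripheral"):
        lines.append(f"{key}: {_CATEGORY_OUT[getattr(sc, key)]}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# validation


def validate_scenario(sc: CaseScenario) -> list[str]:
    """Check all scenario invariants; returns violations in a deterministic
    order (empty list = valid).  Violations are data, not exceptions."""
    violations: list[str] = []
    if not sc.weight_kg > 0:
        violations.append(f"weight must be > 0 kg (got {_fmt_num(sc.weight_kg)})")
    if len(sc.meals) > 6:
        violations.append(f"meal count {len(sc.meals)} exceeds the 6-meal limit")
    for i, m in enumerate(sc.meals, start=1):
        if not 0 <= m.time_min < MINUTES_PER_DAY:
            violations.append(f"meal {i} time outside [0, 24h)")
        if m.grams < 0:
            violations.append(f"meal {i} grams negative")
        elif m.grams > MAX_GRAMS:
            violations.append(f"meal {i} grams exceed {MAX_GRAMS}")
    if len(sc.insulin_slots) > 2:
        violations.append(
            f"insulin preparation count {len(sc.insulin_slots)} exceeds the 2-slot limit")
    registry = load_registry()
    for slot in sc.insulin_slots:
        if slot.preparation not in registry:
            violations.append(f"unknown insulin preparation '{slot.preparation}'")
        if len(slot.injections) > 4:
            violations.append(
                f"{slot.preparation}: {len(slot.injections)} injections exceed "
                "the 4-injection limit")
        for j, (t, d) in enumerate(slot.injections, start=1):
            if not 0 <= t < MINUTES_PER_DAY:
                violations.append(f"{slot.preparation} injection {j} time outside [0, 24h)")
            if d < 0:
                violations.append(f"{slot.preparation} injection {j} dose negative")
            elif d > MAX_DOSE_IU:
                violations.append(
                    f"{slot.preparation} injection {j} dose exceeds {MAX_DOSE_IU} IU")
    for key in ("rtg", "ccr", "hepatic", "peripheral"):
        if getattr(sc, key) not in ("low_reduced", "normal", "high_increased"):
            violations.append(f"{key} category '{getattr(sc, key)}' is not a preset")
    if sc.ccr == "high_increased":
        violations.append("ccr has no high/increased preset")
    return violations


# ---------------------------------------------------------------------------
# packaged cases

_CASES_CACHE: list[CaseScenario] | None = None


def builtin_cases() -> list[CaseScenario]:
    """The 40 packaged virtual patients, ids 0001-0040, all valid."""
    global _CASES_CACHE
    if _CASES_CACHE is None:
        root = importlib.resources.files("glucosim.data") / "cases"
        cases = []
        for entry in sorted(root.iterdir(), key=lambda p: p.name):
            if not entry.name.endswith(".aida"):
                continue
            sc = parse_scenario(entry.read_text())
            problems = validate_scenario(sc)
            if problems:
                raise ScenarioError(
                    f"packaged case {entry.name} is corrupt: {problems[0]}")
            cases.append(sc)
        if len(cases) != 40:
            raise ScenarioError(f"expected 40 packaged cases, found {len(cases)}")
        _CASES_CACHE = cases
    return list(_CASES_CACHE)


def builtin_case(case_id: str) -> CaseScenario:
    for sc in builtin_cases():
        if sc.id == case_id:
            return sc
    raise ScenarioError(f"no packaged case with id {case_id!r}")


# ---------------------------------------------------------------------------
# fixture generator

_MEAL_TIMES = [(7 * 60 + 30, 8 * 60 + 30), (10 * 60, 11 * 60), (12 * 60, 13 * 60 + 30),
               (15 * 60, 16 * 60), (18 * 60, 19 * 60 + 30), (21 * 60 + 30, 23 * 60)]
_FIRST_NAMES = ["Alex", "Sam", "Maria", "Chris", "Pat", "Jan", "Nina", "Omar",
                "Lena", "Ivan", "Rosa", "Kim"]
_LAST_NAMES = ["Smith", "Jones", "Garcia", "Chen", "Patel", "Novak", "Owens",
               "Silva", "Weber", "Kaur"]


def random_scenario(seed: int) -> CaseScenario:
    """Deterministic, always-valid random scenario for testing.

    Repeated seeds cover all preset categories, 1-2 insulin slots and 3-6
    meals at realistic times and amounts.
    """
    rng = np.random.default_rng(seed)
    registry = load_registry()
    by_cat: dict[str, list[str]] = {}
    for name, prep in registry.items():
        by_cat.setdefault(prep.category.value, []).append(name)
    for names in by_cat.values():
        names.sort()

    weight = float(rng.integers(40, 101))
    n_meals = int(rng.integers(3, 7))
    slots_idx = sorted(rng.choice(6, size=n_meals, replace=False).tolist())
    meals = []
    for i in slots_idx:
        lo, hi = _MEAL_TIMES[i]
        t = float(rng.integers(lo // 15, hi // 15 + 1) * 15)
        grams = float(rng.integers(10, 71))
        meals.append(Meal(t, grams))

    slots = []
    style = rng.choice(["basal_bolus", "twice_premixed", "short_only"])
    if style == "twice_premixed":
        prep = str(rng.choice(by_cat["biphasic"]))
        doses = rng.integers(8, 25, size=2)
        slots.append(InsulinSlot(prep, ((8 * 60.0, float(doses[0])),
                                        (18 * 60.0, float(doses[1])))))
    elif style == "basal_bolus":
        short = str(rng.choice(by_cat["short"]))
        basal = str(rng.choice(by_cat["intermediate"] + by_cat["long"]))
        n_boluses = int(rng.integers(2, 5))
        times = sorted(rng.choice([7.5, 12.0, 15.5, 18.5], size=n_boluses,
                                  replace=False).tolist())
        slots.append(InsulinSlot(
            short, tuple((t * 60.0, float(rng.integers(2, 13))) for t in times)))
        slots.append(InsulinSlot(basal, ((22 * 60.0, float(rng.integers(6, 21))),)))
    else:
        short = str(rng.choice(by_cat["short"]))
        times = [7.5, 12.0, 18.5]
        slots.append(InsulinSlot(
            short, tuple((t * 60.0, float(rng.integers(4, 15))) for t in times)))

    cats = ["low_reduced", "normal", "high_increased"]
    sc = CaseScenario(
        id=f"R{seed % 10 ** 4:04d}",
        name=f"{_FIRST_NAMES[int(rng.integers(len(_FIRST_NAMES)))]} "
             f"{_LAST_NAMES[int(rng.integers(len(_LAST_NAMES)))]}",
        description=f"Randomly generated test scenario (seed {seed}).",
        weight_kg=weight,
        meals=meals,
        insulin_slots=slots,
        rtg=cats[int(rng.integers(3))],
        ccr=["low_reduced", "normal"][int(rng.integers(2))],
        hepatic=cats[int(rng.integers(3))],
        peripheral=cats[int(rng.integers(3))],
    )
    problems = validate_scenario(sc)
    if problems:  # pragma: no cover - generator is constructed to be valid
        raise ScenarioError(f"generator produced an invalid scenario: {problems}")
    return sc
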