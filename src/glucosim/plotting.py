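"""Rendering of simulation runs to PNG panels.

Standard display: two panels — blood glucose with carbohydrate bars (and
optional normoglycaemic bounds lines), and plasma insulin with injection
bars.  Advanced display adds the four flux panels (gut glucose absorption,
renal excretion, peripheral utilization, net hepatic glucose balance).
The current run is drawn in red, the previous run (when a comparison is
available) in solid blue; colours are configurable.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering; the CLI never needs a display
import matplotlib.pyplot as plt

from .engine import BGUnits, ComparisonPayload, DisplayMode, EngineError, SimulationRun, convert_bg
from .model import TIME_GRID_H

__all__ = ["render", "CURRENT_COLOR", "PREVIOUS_COLOR"]

CURRENT_COLOR = "red"
PREVIOUS_COLOR = "blue"

_FLUX_PANELS = (
    ("gut_absorption", "Glucose Absorption Rate", "mmol/h"),
    ("renal_excretion", "Renal Excretion", "mmol/h"),
    ("peripheral_utilization", "Peripheral Glucose Utilization", "mmol/h"),
    ("nhgb", "Net Hepatic Glucose Balance", "mmol/h"),
)


def _bg_label(units: BGUnits) -> str:
    return "Blood glucose (mg/dL)" if units is BGUnits.MG_PER_DL else "Blood glucose (mmol/L)"


def _plot_series(ax, run: SimulationRun, attr: str, color: str, label: str,
                 units: BGUnits | None = None) -> None:
    values = getattr(run.result, attr).values
    if units is not None:
        values = convert_bg(values, BGUnits.MMOL_PER_L, units)
    ax.plot(TIME_GRID_H, values, color=color, label=label, lw=1.5)


def render(run: SimulationRun, payload: ComparisonPayload | None,
           options, out_path: Path | str,
           current_color: str = CURRENT_COLOR,
           previous_color: str = PREVIOUS_COLOR) -> Path:
    """Render a run (with optional previous-run overlay) to a PNG file.

    Returns the written path.  Standard display renders 2 panels, advanced
    renders 6; the x-axis spans exactly 0-24 h in every panel.
    """
    out_path = Path(out_path)
    if out_path.suffix.lower() != ".png":
        out_path = out_path.with_suffix(".png")
    previous = payload.previous if payload else None
    bounds = payload.bounds_mmol if payload else options.effective_bounds()
    units = options.bg_units

    advanced = options.display is DisplayMode.ADVANCED
    n_panels = 6 if advanced else 2
    fig, axes = plt.subplots(n_panels, 1, figsize=(8, 2.4 * n_panels), sharex=True)

    ax_bg, ax_ins = axes[0], axes[1]
    if previous is not None:
        _plot_series(ax_bg, previous, "bg", previous_color, "previous run", units)
    _plot_series(ax_bg, run, "bg", current_color, "current run", units)
    if bounds is not None:
        for b in bounds:
            ax_bg.axhline(convert_bg(b, BGUnits.MMOL_PER_L, units),
                          color="gray", ls=":", lw=1)
    for meal in run.scenario.meals:
        ax_bg.bar(meal.time_min / 60.0, meal.grams * 0.05, width=0.3,
                  color="green", align="center")
    ax_bg.set_ylabel(_bg_label(units))
    ax_bg.legend(loc="upper right", fontsize=8)

    if previous is not None:
        _plot_series(ax_ins, previous, "plasma_insulin", previous_color, "previous run")
    _plot_series(ax_ins, run, "plasma_insulin", current_color, "current run")
    for slot in run.scenario.insulin_slots:
        for t, dose in slot.injections:
            ax_ins.bar(t / 60.0, dose * 0.5, width=0.3, color="purple", align="center")
    ax_ins.set_ylabel("Plasma insulin (mU/L)")

    if advanced:
        for ax, (attr, title, unit) in zip(axes[2:], _FLUX_PANELS):
            if previous is not None:
                _plot_series(ax, previous, attr, previous_color, "previous run")
            _plot_series(ax, run, attr, current_color, "current run")
            ax.set_ylabel(f"{title}\n({unit})", fontsize=8)

    for ax in axes:
        ax.set_xlim(0, 24)
    axes[-1].set_xlabel("Time (hours)")
    axes[0].set_title(
        f"Run {run.run_number}: {run.scenario.name or run.scenario.id} — "
        f"HbA1c {run.result.hba1c_percent:.1f}%")
    fig.tight_layout()
    try:
        fig.savefig(out_path, dpi=100)
    except OSError as exc:
        raise EngineError(f"cannot write plot to {out_path}: {exc}") from exc
    finally:
        plt.close(fig)
    return out_path
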