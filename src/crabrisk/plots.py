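"""Optional figures: scenario bands and the sensitivity surface."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
import pandas as pd

from .consumption import Level, ScenarioGridResult
from .harvest import SpeciesGroup

__all__ = ["plot_scenario_bands", "plot_sensitivity_surface"]

_LEVEL_STYLE = {Level.LOW: ":", Level.MEDIUM: "--", Level.HIGH: "-"}


def plot_scenario_bands(grid: ScenarioGridResult, path: str | Path) -> Path:
    """Post-invasion harvest vs density level, one panel per species, one line
    per calorie level with the 95% consumption band."""
    fig, axes = plt.subplots(1, len(SpeciesGroup), figsize=(12, 4), sharex=True)
    x = range(len(Level.ordered()))
    for ax, species in zip(axes, SpeciesGroup):
        for cal_level in Level.ordered():
            outcomes = [
                grid.outcome(species, dl, cal_level) for dl in Level.ordered()
            ]
            baseline = outcomes[0].harvest_after_kg + outcomes[0].loss_kg
            after = [oc.harvest_after_kg for oc in outcomes]
            lo = [max(baseline - oc.estimate.ci_hi_kg, 0.0) for oc in outcomes]
            hi = [max(baseline - oc.estimate.ci_lo_kg, 0.0) for oc in outcomes]
            ax.plot(x, after, _LEVEL_STYLE[cal_level], color="k", label=f"{cal_level.value} cal")
            ax.fill_between(x, lo, hi, alpha=0.15, color="k")
        ax.set_title(species.value.replace("_", " "))
        ax.set_xticks(list(x), [lv.value for lv in Level.ordered()])
        ax.set_xlabel("crab density level")
    axes[0].set_ylabel("harvest after invasion (kg/yr)")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_sensitivity_surface(samples: pd.DataFrame, path: str | Path) -> Path:
    """Hexbin of biomass loss over the (density, intake) plane."""
    fig, ax = plt.subplots(figsize=(6, 5))
    hb = ax.hexbin(
        samples["den"], samples["cal"], C=samples["loss_kg"], gridsize=40, cmap="viridis"
    )
    fig.colorbar(hb, ax=ax, label="harvest biomass loss (kg/yr)")
    ax.set_xlabel("crab density (km$^{-2}$)")
    ax.set_ylabel("intake (cal crab$^{-1}$ yr$^{-1}$)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
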