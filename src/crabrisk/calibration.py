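"""Back-solving per-crab annual calorie intake from published scenario losses.

The consumption kernel is linear in the per-crab annual calorie intake, so an
observed biomass loss at known density and central (range-midpoint) values of
the randomised inputs identifies that intake exactly:

    intake = loss_kg * cal_per_kg / (area * density * diet)

The published scenario table gives one loss per (species, calorie level,
density level). For each (species, calorie level) the three density cells are
combined by least squares through the origin of loss = k * density — the
published cells are rounded to 0.01e6 kg, so no single cell is authoritative.
Cells where the published post-invasion harvest is zero are floored: they
censor the loss (only a lower bound on intake) and are excluded from the fit.

A caveat found while building this package: the published medium-density
cells for clams and mussels sit far below the loss-proportional-to-density
line that their low/high-density cells follow, so the least-squares intake
cannot reproduce every published cell to its printed rounding, and the fitted
mussel intake is not strictly increasing across calorie levels once the
floored high/high cell is excluded (a warning is emitted). See
docs/methods.md for the full analysis.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, Tuple

import pandas as pd

from .consumption import Level, ScenarioLevels, UncertainInputs
from .errors import CalibrationError, CalibrationWarning, ValidationError
from .harvest import SpeciesGroup

__all__ = [
    "LossObservation",
    "REFERENCE_BASELINES",
    "packaged_loss_observations",
    "packaged_reference_totals",
    "backsolve_cal",
    "calibrate_levels",
    "calibrated_levels",
]

#: Published baselines of the scenario table (kg/yr, USD/yr); the "all" row is
#: the published grand total that the published percent losses are quoted
#: against. (These differ in the last digit from the harvest-table canonical
#: totals because the source rounds to 0.01e6.)
REFERENCE_BASELINES: dict[str, tuple[float, float]] = {
    SpeciesGroup.HARDSHELL_CLAM.value: (3.41e6, 18.30e6),
    SpeciesGroup.OYSTER.value: (1.35e6, 14.10e6),
    SpeciesGroup.MUSSEL.value: (1.29e6, 4.80e6),
    "all": (6.05e6, 37.26e6),
}


@dataclass(frozen=True)
class LossObservation:
    """One published scenario cell: biomass loss for a species at one
    (calorie level, density level); ``floored`` marks a censored cell."""

    species_group: SpeciesGroup
    density_level: Level
    calorie_level: Level
    loss_kg: float
    floored: bool = False

    def __post_init__(self) -> None:
        # loss <= species baseline is a property of the table the cell came
        # from; it is checked where observations are generated or loaded.
        if self.loss_kg < 0.0:
            raise ValidationError("loss_kg must be non-negative")


def _reference_frame() -> pd.DataFrame:
    ref = resources.files("crabrisk.data").joinpath("reference_scenario_losses.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, comment="#")


def packaged_loss_observations() -> list[LossObservation]:
    """Species-level loss observations from the published scenario table."""
    df = _reference_frame()
    out = []
    for row in df.itertuples(index=False):
        if row.species_group == "all":
            continue
        out.append(
            LossObservation(
                species_group=SpeciesGroup(row.species_group),
                density_level=Level(row.density_level),
                calorie_level=Level(row.calorie_level),
                loss_kg=float(row.loss_kg),
                floored=bool(row.floored),
            )
        )
    return out


def packaged_reference_totals() -> pd.DataFrame:
    """Published per-cell grand-total losses (kg and USD) with loss fractions
    relative to the published baseline totals."""
    df = _reference_frame()
    df = df[df.species_group == "all"].copy().reset_index(drop=True)
    base_kg, base_usd = REFERENCE_BASELINES["all"]
    df["kg_loss_fraction"] = df["loss_kg"] / base_kg
    df["revenue_loss_fraction"] = df["loss_usd"] / base_usd
    return df[
        [
            "calorie_level",
            "density_level",
            "loss_kg",
            "loss_usd",
            "kg_loss_fraction",
            "revenue_loss_fraction",
        ]
    ]


def backsolve_cal(
    loss_kg: float,
    density_per_km2: float,
    area_km2: float,
    diet_fraction: float,
    cal_per_kg: float,
) -> float:
    """Invert the consumption kernel for per-crab annual intake (cal/crab/yr).

    Exact for a noiseless loss: feeding the result back through
    ``consumption_point`` at the same central values reproduces ``loss_kg``
    to machine precision.
    """
    if density_per_km2 <= 0.0:
        raise ValidationError("density must be positive to back-solve intake")
    if area_km2 <= 0.0 or diet_fraction <= 0.0 or cal_per_kg <= 0.0:
        raise ValidationError("central values must be positive to back-solve intake")
    if loss_kg < 0.0:
        raise ValidationError("loss_kg must be non-negative")
    return loss_kg * cal_per_kg / (area_km2 * density_per_km2 * diet_fraction)


def calibrate_levels(
    observations: Iterable[LossObservation],
    uncertain: UncertainInputs | None = None,
    densities: Dict[Level, float] | None = None,
) -> Dict[Tuple[SpeciesGroup, Level], float]:
    """Least-squares intake (cal/crab/yr) per (species, calorie level).

    For each group, fit loss = k * density through the origin over the
    non-floored density cells (k = sum(d*l)/sum(d^2)), then convert the slope
    to an intake at central parameter values (area and diet at range
    midpoints, cal_per_kg at the species range midpoint — the expectation of
    each uniform). Raises :class:`CalibrationError` when every cell of a group
    is floored; warns when fitted intakes are not strictly increasing in
    calorie level.
    """
    uncertain = uncertain if uncertain is not None else UncertainInputs()
    if densities is None:
        densities = ScenarioLevels().densities
    groups: Dict[Tuple[SpeciesGroup, Level], list[LossObservation]] = {}
    for obs in observations:
        groups.setdefault((obs.species_group, obs.calorie_level), []).append(obs)

    calories: Dict[Tuple[SpeciesGroup, Level], float] = {}
    for (species, cal_level), obs_list in groups.items():
        usable = [o for o in obs_list if not o.floored]
        if not usable:
            raise CalibrationError(
                f"all observations floored for ({species.value}, {cal_level.value}); "
                "intake is only bounded below and cannot be calibrated"
            )
        num = sum(densities[o.density_level] * o.loss_kg for o in usable)
        den = sum(densities[o.density_level] ** 2 for o in usable)
        k = num / den  # kg lost per (crab/km^2)
        calories[(species, cal_level)] = backsolve_cal(
            loss_kg=k,
            density_per_km2=1.0,
            area_km2=uncertain.area_mid,
            diet_fraction=uncertain.diet_mid,
            cal_per_kg=uncertain.cal_per_kg_mid(species),
        )

    for species in {sp for sp, _ in calories}:
        seq = [
            calories[(species, lv)] for lv in Level.ordered() if (species, lv) in calories
        ]
        if any(b <= a for a, b in zip(seq, seq[1:])):
            warnings.warn(
                f"calibrated intake for {species.value} is not strictly increasing "
                f"across calorie levels: {seq}; the source scenario table is not "
                "consistent with loss proportional to density in every cell",
                CalibrationWarning,
                stacklevel=2,
            )
    return calories


def calibrated_levels(
    uncertain: UncertainInputs | None = None,
    densities: Dict[Level, float] | None = None,
) -> ScenarioLevels:
    """ScenarioLevels with intakes calibrated from the packaged published losses."""
    levels = ScenarioLevels() if densities is None else ScenarioLevels(densities=densities)
    levels.calories = calibrate_levels(
        packaged_loss_observations(), uncertain=uncertain, densities=levels.densities
    )
    return levels
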