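"""Density x intake sensitivity surface for total harvest-biomass loss.

Instead of three discrete levels, crab density and per-crab annual intake
range freely and uniformly from zero to their high estimates, while the
*total* diet fraction on harvested shellfish spans 0.60-1.00 (split equally
across the three species groups). Each of the 10,000 samples draws density,
intake, total diet, harvest area and per-species calorie densities, computes
per-species consumption capped at the species baseline, and sums the capped
losses. A single intake scalar applies to every species in this analysis
(the surface has one calorie axis); species differences enter through their
calorie-per-kg draws and baselines.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import package_defaults
from .consumption import Level, ScenarioLevels, UncertainInputs, _uniform
from .errors import ConfigurationError, ValidationError
from .harvest import HarvestTable, SpeciesGroup

__all__ = ["SensitivityBounds", "default_bounds", "surface_loss_kg", "sensitivity_surface"]


@dataclass(frozen=True)
class SensitivityBounds:
    """Upper bounds for the free axes and the total-diet range."""

    den_high: float = 100_000.0
    cal_high: float = 0.0  # cal/crab/yr; must be populated (no published default)
    diet_total_lo: float = 0.60
    diet_total_hi: float = 1.00

    def __post_init__(self) -> None:
        if self.den_high < 0.0:
            raise ValidationError("den_high must be non-negative")
        if not 0.0 <= self.diet_total_lo <= self.diet_total_hi <= 1.0:
            raise ValidationError("diet_total bounds must satisfy 0 <= lo <= hi <= 1")


def default_bounds(levels: ScenarioLevels) -> SensitivityBounds:
    """Bounds from the packaged defaults, with the intake ceiling taken as the
    maximum calibrated high-level intake across species."""
    block = package_defaults()["sensitivity"]
    highs = [
        levels.calories[(sp, Level.HIGH)]
        for sp in SpeciesGroup
        if (sp, Level.HIGH) in levels.calories
    ]
    if not highs:
        raise ConfigurationError(
            "sensitivity bounds need high-level intakes; calibrate or configure calories"
        )
    return SensitivityBounds(
        den_high=float(block["den_high"]),
        cal_high=max(highs),
        diet_total_lo=float(block["diet_total_lo"]),
        diet_total_hi=float(block["diet_total_hi"]),
    )


def surface_loss_kg(
    density_per_km2,
    cal_per_crab_yr,
    diet_total,
    area_km2,
    cal_per_kg_by_species,
    baselines_kg,
):
    """Deterministic surface kernel: summed species-capped biomass loss (kg/yr).

    Accepts scalars or equal-length numpy arrays; ``cal_per_kg_by_species``
    and ``baselines_kg`` map species -> value (or array of values).
    """
    total = 0.0
    for species in SpeciesGroup:
        per_species_diet = np.asarray(diet_total) / len(SpeciesGroup)
        consumption = (
            np.asarray(area_km2)
            * np.asarray(density_per_km2)
            * np.asarray(cal_per_crab_yr)
            * per_species_diet
            / np.asarray(cal_per_kg_by_species[species])
        )
        total = total + np.minimum(consumption, baselines_kg[species])
    return total


def sensitivity_surface(
    table: HarvestTable,
    bounds: SensitivityBounds,
    uncertain: UncertainInputs | None = None,
    n: int = 10_000,
    seed: int = 1,
) -> pd.DataFrame:
    """Monte-Carlo sample of the loss surface; one row per sample.

    Columns: den (crabs/km^2), cal (cal/crab/yr), diet_total, area (km^2),
    loss_kg (capped at the total baseline). Reproducible given ``seed``.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if bounds.cal_high <= 0.0:
        raise ConfigurationError("bounds.cal_high must be positive; calibrate intakes first")
    uncertain = uncertain if uncertain is not None else UncertainInputs()
    rng = np.random.default_rng(seed)
    den = _uniform(rng, 0.0, bounds.den_high, n)
    cal = _uniform(rng, 0.0, bounds.cal_high, n)
    diet_total = _uniform(rng, bounds.diet_total_lo, bounds.diet_total_hi, n)
    area_lo, area_hi = uncertain.area_range
    area = _uniform(rng, area_lo, area_hi, n)
    cal_per_kg = {
        sp: _uniform(rng, *uncertain.cal_per_kg[sp], n) for sp in SpeciesGroup
    }
    baselines = {sp: table.species_total(sp).harvest_kg for sp in SpeciesGroup}
    loss = surface_loss_kg(den, cal, diet_total, area, cal_per_kg, baselines)
    return pd.DataFrame(
        {"den": den, "cal": cal, "diet_total": diet_total, "area": area, "loss_kg": loss}
    )
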