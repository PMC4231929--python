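"""Known-truth synthetic data for end-to-end pipeline testing.

Two generators emulate the shapes of the study inputs without reusing them:

* harvest tables — per-area biomass drawn log-uniformly (published per-area
  biomass spans roughly two orders of magnitude), prices uniform within a
  species range, and revenue exactly price x biomass, so the revenue
  invariant is strict where the published table is internally inconsistent;
* loss observations — the forward consumption kernel evaluated at central
  (range-midpoint) parameters with known true densities and intakes, floored
  at the species baseline with the censoring flag set.

Because the model is linear and the synthetic losses are noiseless,
calibration must recover the true intakes exactly on non-floored cells;
that round trip is the module's main correctness check.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .calibration import LossObservation
from .consumption import Level, ScenarioLevels, UncertainInputs, consumption_point
from .errors import ConfigurationError, ValidationError
from .harvest import HarvestRecord, HarvestTable, SpeciesGroup

__all__ = ["SyntheticSpec", "generate_harvest_table", "generate_loss_observations"]


def _default_biomass_scales() -> Dict[SpeciesGroup, float]:
    # Geometric centres per species, tuned to the magnitude of the 2009 table
    return {
        SpeciesGroup.HARDSHELL_CLAM: 3.5e5,
        SpeciesGroup.OYSTER: 1.5e5,
        SpeciesGroup.MUSSEL: 5.0e4,
    }


def _default_price_ranges() -> Dict[SpeciesGroup, Tuple[float, float]]:
    # USD/kg spans of the published per-area prices
    return {
        SpeciesGroup.HARDSHELL_CLAM: (3.0, 6.0),
        SpeciesGroup.OYSTER: (2.0, 12.0),
        SpeciesGroup.MUSSEL: (4.0, 8.0),
    }


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study: table shape, scales, and true scenario."""

    n_areas: int = 6
    biomass_scale_kg: Dict[SpeciesGroup, float] = field(default_factory=_default_biomass_scales)
    biomass_dispersion_decades: float = 0.75
    price_range: Dict[SpeciesGroup, Tuple[float, float]] = field(
        default_factory=_default_price_ranges
    )
    area_km2_range: Tuple[float, float] = (40.0, 130.0)
    true_levels: ScenarioLevels | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_areas < 0:
            raise ValidationError("n_areas must be non-negative")
        if self.biomass_dispersion_decades < 0.0:
            raise ValidationError("biomass_dispersion_decades must be non-negative")
        for sp, scale in self.biomass_scale_kg.items():
            if not scale > 0.0:
                raise ValidationError(f"biomass scale for {sp} must be positive")
        for sp, (lo, hi) in self.price_range.items():
            if not 0.0 <= lo <= hi:
                raise ValidationError(f"price range for {sp} must satisfy 0 <= lo <= hi")


def generate_harvest_table(spec: SyntheticSpec) -> HarvestTable:
    """A harvest table with ``n_areas`` areas per species and exact revenues.

    Biomass per (species, area) is ``scale * 10**U(-d, +d)`` with ``d`` the
    dispersion in decades; price is uniform in the species range; revenue is
    exactly price x biomass, so species totals are exact sums. Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[HarvestRecord] = []
    for species in SpeciesGroup:
        scale = spec.biomass_scale_kg[species]
        price_lo, price_hi = spec.price_range[species]
        for i in range(spec.n_areas):
            d = spec.biomass_dispersion_decades
            biomass = scale * 10.0 ** (-d + 2.0 * d * rng.random())
            price = price_lo + (price_hi - price_lo) * rng.random()
            area_lo, area_hi = spec.area_km2_range
            area = area_lo + (area_hi - area_lo) * rng.random()
            records.append(
                HarvestRecord(
                    species_group=species,
                    action_area=f"synthetic_area_{i + 1:02d}",
                    area_km2=area,
                    harvest_kg=biomass,
                    price_usd_per_kg=price,
                    revenue_usd=biomass * price,
                )
            )
    return HarvestTable(records)


def generate_loss_observations(
    spec: SyntheticSpec,
    table: HarvestTable,
    uncertain: UncertainInputs | None = None,
) -> list[LossObservation]:
    """Noiseless scenario losses from the forward kernel at central parameters.

    Losses beyond a species baseline are floored there and flagged, mirroring
    how a published table censors consumption at the harvestable biomass.
    """
    if spec.true_levels is None:
        raise ConfigurationError("spec.true_levels with calories must be set")
    uncertain = uncertain if uncertain is not None else UncertainInputs()
    levels = spec.true_levels
    out: list[LossObservation] = []
    for species in SpeciesGroup:
        baseline_kg = table.species_total(species).harvest_kg
        for density_level in Level.ordered():
            for calorie_level in Level.ordered():
                loss = consumption_point(
                    area_km2=uncertain.area_mid,
                    density_per_km2=levels.density(density_level),
                    cal_per_crab_yr=levels.calorie(species, calorie_level),
                    diet_fraction=uncertain.diet_mid,
                    cal_per_kg=uncertain.cal_per_kg_mid(species),
                )
                floored = loss > baseline_kg
                out.append(
                    LossObservation(
                        species_group=species,
                        density_level=density_level,
                        calorie_level=calorie_level,
                        loss_kg=min(loss, baseline_kg),
                        floored=floored,
                    )
                )
    return out
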