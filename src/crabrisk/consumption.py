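"""Green-crab consumption model and Monte-Carlo scenario grid.

The static bioenergetic kernel is

    consumption (kg/yr) = area x density x annual_calories x diet / cal_per_kg

with ``area`` the harvest ground (km^2), ``density`` adult crabs per km^2,
``annual_calories`` the calories one crab consumes per year, ``diet`` the
fraction of that intake taken from the focal species, and ``cal_per_kg`` the
calorie density of that species' landed wet weight.

Uncertainty is handled two ways, mirroring the study design: density and
annual calories take three discrete scenario levels (low/medium/high) and are
held fixed within a cell, while area, diet and cal_per_kg are drawn from
uniform ranges, 10,000 times per cell by default. The reported interval is
the 2.5th-97.5th percentile band of the sampled consumption distribution:
with uniform input ranges (not sampling error) a standard-error-of-the-mean
interval would collapse toward zero and carry no information about the band.

Uniform draws are generated as ``lo + (hi - lo) * u`` with ``u`` from the
seeded generator, so for a fixed seed widening any range rescales the same
underlying variates monotonically — intervals can only widen.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from .config import package_defaults
from .energetics import default_cal_per_kg_ranges
from .errors import ConfigurationError, ValidationError
from .harvest import HarvestTable, SpeciesGroup

__all__ = [
    "Level",
    "ScenarioLevels",
    "UncertainInputs",
    "MCSettings",
    "ConsumptionEstimate",
    "ScenarioOutcome",
    "CellTotal",
    "ScenarioGridResult",
    "consumption_point",
    "run_scenario",
    "apply_consumption",
    "scenario_grid",
]


class Level(str, enum.Enum):
    """Scenario level for invasion density and per-crab calorie intake."""

    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def ordered(cls) -> tuple["Level", "Level", "Level"]:
        return (cls.LOW, cls.MEDIUM, cls.HIGH)


def _default_densities() -> Dict[Level, float]:
    block = package_defaults()["scenario_densities"]
    return {lv: float(block[lv.value]) for lv in Level.ordered()}


@dataclass
class ScenarioLevels:
    """Discrete scenario settings: crabs/km^2 per level and cal/crab/yr per
    (species, level). Calorie values have no published defaults; they come from
    :func:`crabrisk.calibration.calibrated_levels` or user configuration."""

    densities: Dict[Level, float] = field(default_factory=_default_densities)
    calories: Dict[Tuple[SpeciesGroup, Level], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ordered = [self.densities.get(lv) for lv in Level.ordered()]
        if any(v is None for v in ordered):
            raise ConfigurationError("densities must define low, medium and high levels")
        if not (0.0 < ordered[0] < ordered[1] < ordered[2]):
            raise ConfigurationError(
                f"densities must be strictly increasing low<medium<high, got {ordered}"
            )
        for key, cal in self.calories.items():
            if not cal >= 0.0:
                raise ConfigurationError(f"calorie value for {key} must be non-negative")

    def density(self, level: Level) -> float:
        return self.densities[Level(level)]

    def calorie(self, species: SpeciesGroup, level: Level) -> float:
        try:
            return self.calories[(SpeciesGroup(species), Level(level))]
        except KeyError:
            raise ConfigurationError(
                f"no calorie value configured for ({species}, {level}); "
                "run calibration or supply scenario calories in the config"
            ) from None

    def calories_monotone(self) -> bool:
        """True when calories increase strictly low<medium<high for every species present."""
        for species in {sp for sp, _ in self.calories}:
            seq = [
                self.calories.get((species, lv))
                for lv in Level.ordered()
                if (species, lv) in self.calories
            ]
            if any(b <= a for a, b in zip(seq, seq[1:])):
                return False
        return True


def _default_uncertain_kwargs() -> dict:
    block = package_defaults()["uncertain_inputs"]
    return {
        "area_mid": float(block["area_km2_mid"]),
        "area_halfwidth": float(block["area_km2_halfwidth"]),
        "diet_lo": float(block["diet_lo"]),
        "diet_hi": float(block["diet_hi"]),
    }


@dataclass(frozen=True)
class UncertainInputs:
    """Uniform ranges for the randomised inputs: harvest area (km^2), per-species
    diet fraction, and per-species calories per kg of wet weight."""

    area_mid: float = 523.71
    area_halfwidth: float = 75.0
    diet_lo: float = 0.20
    diet_hi: float = 0.35
    cal_per_kg: Mapping[SpeciesGroup, Tuple[float, float]] = field(
        default_factory=default_cal_per_kg_ranges
    )

    def __post_init__(self) -> None:
        if not self.area_mid - self.area_halfwidth > 0.0:
            raise ValidationError("area range must stay positive (mid - halfwidth > 0)")
        if not (0.0 <= self.diet_lo <= self.diet_hi <= 1.0):
            raise ValidationError("diet bounds must satisfy 0 <= lo <= hi <= 1")
        for sp, (lo, hi) in self.cal_per_kg.items():
            if not (0.0 < lo <= hi):
                raise ValidationError(f"cal_per_kg range for {sp} must satisfy 0 < lo <= hi")

    @property
    def area_range(self) -> Tuple[float, float]:
        return (self.area_mid - self.area_halfwidth, self.area_mid + self.area_halfwidth)

    @property
    def diet_mid(self) -> float:
        return 0.5 * (self.diet_lo + self.diet_hi)

    def cal_per_kg_mid(self, species: SpeciesGroup) -> float:
        lo, hi = self.cal_per_kg[SpeciesGroup(species)]
        return 0.5 * (lo + hi)


@dataclass(frozen=True)
class MCSettings:
    """Monte-Carlo replication count and seed."""

    n_reps: int = 10_000
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")


@dataclass(frozen=True)
class ConsumptionEstimate:
    """MC mean and 95% (percentile) interval of kg consumed, one scenario cell."""

    species_group: SpeciesGroup
    density_level: Level
    calorie_level: Level
    mean_kg: float
    ci_lo_kg: float
    ci_hi_kg: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_lo_kg <= self.mean_kg <= self.ci_hi_kg):
            raise ValidationError(
                "consumption estimate must satisfy 0 <= ci_lo <= mean <= ci_hi, got "
                f"({self.ci_lo_kg}, {self.mean_kg}, {self.ci_hi_kg})"
            )


@dataclass(frozen=True)
class ScenarioOutcome:
    """Post-invasion harvest for one species in one scenario cell.

    Revenue is assumed to fall in parallel with harvested biomass, so the
    revenue loss fraction equals the biomass loss fraction; both are capped at
    1 (consumption cannot remove more than the harvestable baseline).
    """

    species_group: SpeciesGroup
    density_level: Level
    calorie_level: Level
    harvest_after_kg: float
    revenue_after_usd: float
    loss_kg: float
    loss_usd: float
    loss_fraction: float
    estimate: ConsumptionEstimate


def consumption_point(
    area_km2: float,
    density_per_km2: float,
    cal_per_crab_yr: float,
    diet_fraction: float,
    cal_per_kg: float,
) -> float:
    """Deterministic consumption kernel (kg/yr); linear in each numerator input."""
    if cal_per_kg <= 0.0:
        raise ValidationError("cal_per_kg must be positive")
    for name, value in (
        ("area_km2", area_km2),
        ("density_per_km2", density_per_km2),
        ("cal_per_crab_yr", cal_per_crab_yr),
        ("diet_fraction", diet_fraction),
    ):
        if value < 0.0:
            raise ValidationError(f"{name} must be non-negative, got {value!r}")
    return area_km2 * density_per_km2 * cal_per_crab_yr * diet_fraction / cal_per_kg


def _uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    # lo + (hi-lo)*u keeps draws monotone in the bounds for a fixed generator state
    return lo + (hi - lo) * rng.random(n)


def sample_consumption(
    species: SpeciesGroup,
    density_level: Level,
    calorie_level: Level,
    uncertain: UncertainInputs,
    levels: ScenarioLevels,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """The raw MC consumption sample (kg/yr) for one scenario cell."""
    density = levels.density(density_level)
    calories = levels.calorie(species, calorie_level)
    area_lo, area_hi = uncertain.area_range
    calkg_lo, calkg_hi = uncertain.cal_per_kg[SpeciesGroup(species)]
    area = _uniform(rng, area_lo, area_hi, n_reps)
    diet = _uniform(rng, uncertain.diet_lo, uncertain.diet_hi, n_reps)
    cal_per_kg = _uniform(rng, calkg_lo, calkg_hi, n_reps)
    return area * density * calories * diet / cal_per_kg


def run_scenario(
    species: SpeciesGroup,
    density_level: Level,
    calorie_level: Level,
    uncertain: UncertainInputs | None = None,
    levels: ScenarioLevels | None = None,
    mc: MCSettings | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> ConsumptionEstimate:
    """MC consumption estimate for one (species, density level, calorie level) cell.

    Density and annual calories are fixed at their scenario values; area, diet
    and cal_per_kg are drawn uniformly and independently. Reproducible given
    the seed in ``mc`` (or an explicitly shared ``rng``).
    """
    uncertain = uncertain if uncertain is not None else UncertainInputs()
    if levels is None:
        raise ConfigurationError("run_scenario requires ScenarioLevels with calories set")
    mc = mc if mc is not None else MCSettings()
    if rng is None:
        rng = np.random.default_rng(mc.seed)
    sample = sample_consumption(
        species, density_level, calorie_level, uncertain, levels, mc.n_reps, rng
    )
    ci_lo, ci_hi = np.percentile(sample, [2.5, 97.5])
    mean = float(sample.mean())
    # percentile interpolation can differ from the mean by one ulp when the
    # sample is (near-)constant; clamp so the bracket invariant holds exactly
    return ConsumptionEstimate(
        species_group=SpeciesGroup(species),
        density_level=Level(density_level),
        calorie_level=Level(calorie_level),
        mean_kg=mean,
        ci_lo_kg=min(float(ci_lo), mean),
        ci_hi_kg=max(float(ci_hi), mean),
    )


def apply_consumption(
    baseline_kg: float, baseline_usd: float, estimate: ConsumptionEstimate
) -> ScenarioOutcome:
    """Translate mean consumption into post-invasion harvest and revenue.

    Harvest is floored at zero (consumption beyond the baseline removes the
    harvest, not more) and revenue scales with the biomass loss fraction.
    """
    if baseline_kg < 0.0 or baseline_usd < 0.0:
        raise ValidationError("baselines must be non-negative")
    loss_kg = min(estimate.mean_kg, baseline_kg)
    loss_fraction = loss_kg / baseline_kg if baseline_kg > 0.0 else 0.0
    loss_usd = baseline_usd * loss_fraction
    return ScenarioOutcome(
        species_group=estimate.species_group,
        density_level=estimate.density_level,
        calorie_level=estimate.calorie_level,
        harvest_after_kg=baseline_kg - loss_kg,
        revenue_after_usd=baseline_usd - loss_usd,
        loss_kg=loss_kg,
        loss_usd=loss_usd,
        loss_fraction=loss_fraction,
        estimate=estimate,
    )


@dataclass(frozen=True)
class CellTotal:
    """Across-species totals for one (density level, calorie level) cell."""

    density_level: Level
    calorie_level: Level
    loss_kg: float
    loss_usd: float
    kg_loss_fraction: float
    revenue_loss_fraction: float


class ScenarioGridResult:
    """27 species-level outcomes plus 9 per-cell totals."""

    def __init__(
        self,
        outcomes: list[ScenarioOutcome],
        cell_totals: Dict[Tuple[Level, Level], CellTotal],
        baseline_kg: float,
        baseline_usd: float,
    ) -> None:
        self.outcomes = outcomes
        self.cell_totals = cell_totals
        self.baseline_kg = baseline_kg
        self.baseline_usd = baseline_usd

    def outcome(
        self, species: SpeciesGroup, density_level: Level, calorie_level: Level
    ) -> ScenarioOutcome:
        for oc in self.outcomes:
            if (
                oc.species_group is SpeciesGroup(species)
                and oc.density_level is Level(density_level)
                and oc.calorie_level is Level(calorie_level)
            ):
                return oc
        raise KeyError((species, density_level, calorie_level))

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-species rows: one row per species x density x calorie cell."""
        rows = []
        for oc in self.outcomes:
            rows.append(
                {
                    "species_group": oc.species_group.value,
                    "density_level": oc.density_level.value,
                    "calorie_level": oc.calorie_level.value,
                    "harvest_after_kg": oc.harvest_after_kg,
                    "revenue_after_usd": oc.revenue_after_usd,
                    "loss_kg": oc.loss_kg,
                    "loss_usd": oc.loss_usd,
                    "loss_fraction": oc.loss_fraction,
                    "consumption_mean_kg": oc.estimate.mean_kg,
                    "consumption_ci_lo_kg": oc.estimate.ci_lo_kg,
                    "consumption_ci_hi_kg": oc.estimate.ci_hi_kg,
                }
            )
        return pd.DataFrame(rows)

    def totals_frame(self) -> pd.DataFrame:
        rows = []
        for (dl, cl), cell in self.cell_totals.items():
            rows.append(
                {
                    "density_level": dl.value,
                    "calorie_level": cl.value,
                    "loss_kg": cell.loss_kg,
                    "loss_usd": cell.loss_usd,
                    "kg_loss_fraction": cell.kg_loss_fraction,
                    "revenue_loss_fraction": cell.revenue_loss_fraction,
                }
            )
        return pd.DataFrame(rows)


def scenario_grid(
    table: HarvestTable,
    levels: ScenarioLevels,
    uncertain: UncertainInputs | None = None,
    mc: MCSettings | None = None,
) -> ScenarioGridResult:
    """Full 3x3 scenario grid over all species in ``table``.

    A single generator seeded from ``mc.seed`` feeds every cell, and cells are
    evaluated in a fixed (species, density, calorie) order, so results do not
    depend on evaluation laziness. Per-cell totals sum capped species losses.
    """
    uncertain = uncertain if uncertain is not None else UncertainInputs()
    mc = mc if mc is not None else MCSettings()
    rng = np.random.default_rng(mc.seed)
    grand = table.grand_total()
    outcomes: list[ScenarioOutcome] = []
    for species in SpeciesGroup:
        baseline = table.species_total(species)
        for density_level in Level.ordered():
            for calorie_level in Level.ordered():
                est = run_scenario(
                    species, density_level, calorie_level, uncertain, levels, mc, rng=rng
                )
                outcomes.append(
                    apply_consumption(baseline.harvest_kg, baseline.revenue_usd, est)
                )
    cell_totals: Dict[Tuple[Level, Level], CellTotal] = {}
    for density_level in Level.ordered():
        for calorie_level in Level.ordered():
            cell = [
                oc
                for oc in outcomes
                if oc.density_level is density_level and oc.calorie_level is calorie_level
            ]
            loss_kg = sum(oc.loss_kg for oc in cell)
            loss_usd = sum(oc.loss_usd for oc in cell)
            cell_totals[(density_level, calorie_level)] = CellTotal(
                density_level=density_level,
                calorie_level=calorie_level,
                loss_kg=loss_kg,
                loss_usd=loss_usd,
                kg_loss_fraction=loss_kg / grand.harvest_kg,
                revenue_loss_fraction=loss_usd / grand.revenue_usd,
            )
    return ScenarioGridResult(outcomes, cell_totals, grand.harvest_kg, grand.revenue_usd)
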