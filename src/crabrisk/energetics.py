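"""Shellfish flesh energy densities.

Green-crab consumption is modelled in calories, while harvest statistics are
landed wet weight (WW), so each species needs a calories-per-kilogram range.
Literature reports calorie density per mg of ash-free dry weight (AFDW) and
AFDW:WW conversions; the conversions here are interpreted as AFDW expressed as
a *percent* of wet weight (e.g. 5.2 means AFDW is 5.2% of WW). The absolute
scale of this choice is absorbed downstream when per-crab annual intake is
calibrated against published scenario outcomes, but it is stated explicitly
because the source reviews do not fix the direction of the conversion.

``cal`` throughout means the small (gram) calorie, matching cal mg^-1 sources.
"""
from __future__ import annotations

from dataclasses import dataclass

from .config import package_defaults
from .errors import ValidationError
from .harvest import SpeciesGroup

__all__ = ["SpeciesEnergetics", "default_energetics", "default_cal_per_kg_ranges"]

#: mg of flesh per kg of flesh.
MG_PER_KG = 1.0e6


@dataclass(frozen=True)
class SpeciesEnergetics:
    """Calorie density of flesh and AFDW fraction of wet weight for one species."""

    species_group: SpeciesGroup
    cal_per_mg_afdw: float
    afdw_fraction_lo: float
    afdw_fraction_hi: float

    def __post_init__(self) -> None:
        if not self.cal_per_mg_afdw > 0.0:
            raise ValidationError("cal_per_mg_afdw must be positive")
        for name in ("afdw_fraction_lo", "afdw_fraction_hi"):
            frac = getattr(self, name)
            if not 0.0 < frac <= 1.0:
                raise ValidationError(f"{name} must lie in (0, 1], got {frac!r}")
        if self.afdw_fraction_lo > self.afdw_fraction_hi:
            raise ValidationError("afdw_fraction_lo must not exceed afdw_fraction_hi")

    @classmethod
    def from_afdw_percent(
        cls, species_group: SpeciesGroup, cal_per_mg_afdw: float, percent_lo: float, percent_hi: float
    ) -> "SpeciesEnergetics":
        """Build from AFDW expressed as percent of wet weight (the source convention)."""
        return cls(species_group, cal_per_mg_afdw, percent_lo / 100.0, percent_hi / 100.0)

    def cal_per_kg_range(self) -> tuple[float, float]:
        """Calories per kg of landed wet weight, (lo, hi).

        cal kg^-1 = cal mg^-1 AFDW x (AFDW fraction of WW) x 1e6 mg kg^-1.
        """
        lo = self.cal_per_mg_afdw * self.afdw_fraction_lo * MG_PER_KG
        hi = self.cal_per_mg_afdw * self.afdw_fraction_hi * MG_PER_KG
        return (lo, hi)

    def cal_per_kg_midpoint(self) -> float:
        lo, hi = self.cal_per_kg_range()
        return 0.5 * (lo + hi)


def default_energetics() -> dict[SpeciesGroup, SpeciesEnergetics]:
    """Packaged defaults: clams 6.15, oysters 4.85, mussels 5.47 cal/mg AFDW with
    AFDW at 5.2-6.4%, 1.7%, and 2.5-6.7% of wet weight respectively."""
    block = package_defaults()["energetics"]
    out: dict[SpeciesGroup, SpeciesEnergetics] = {}
    for species in SpeciesGroup:
        entry = block[species.value]
        lo, hi = entry["afdw_percent_of_wet_weight"]
        out[species] = SpeciesEnergetics.from_afdw_percent(
            species, float(entry["cal_per_mg_afdw"]), float(lo), float(hi)
        )
    return out


def default_cal_per_kg_ranges() -> dict[SpeciesGroup, tuple[float, float]]:
    """Per-species (lo, hi) calories per kg of wet weight under the defaults."""
    return {sp: e.cal_per_kg_range() for sp, e in default_energetics().items()}
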