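"""Baseline commercial shellfish harvest of Puget Sound.

The unit of analysis is one (species group, action area) row: annual landed
biomass, average price, and revenue. The packaged baseline is the 2009 PacFIN
harvest apportioned to Puget Sound Partnership action areas (South Central
Puget Sound excluded; it holds ~0.4% of the harvest area).

Published per-area rows do not always sum to the published species totals
(the mussel rows sum to ~0.835e6 kg against a published total of 1.288e6 kg),
so a table carries *canonical* species totals separately and every downstream
computation uses those, never re-derived area sums.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "SpeciesGroup",
    "HarvestRecord",
    "SpeciesTotal",
    "GrandTotal",
    "HarvestTable",
    "load_harvest_table",
    "write_harvest_table",
    "packaged_baseline",
    "CANONICAL_SPECIES_TOTALS",
]


class SpeciesGroup(str, enum.Enum):
    """Commercially harvested shellfish groups vulnerable to green crab predation."""

    HARDSHELL_CLAM = "hardshell_clam"
    OYSTER = "oyster"
    MUSSEL = "mussel"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: CSV schema, with unit-suffixed column names.
REQUIRED_COLUMNS = (
    "species_group",
    "action_area",
    "area_km2",
    "harvest_kg",
    "price_usd_per_kg",
    "revenue_usd",
)

#: Published species-total biomass (kg/yr) and revenue (USD/yr) for the 2009
#: Puget Sound baseline. These are authoritative for downstream computation.
CANONICAL_SPECIES_TOTALS: dict[SpeciesGroup, tuple[float, float]] = {
    SpeciesGroup.HARDSHELL_CLAM: (3_411_000.0, 18_340_000.0),
    SpeciesGroup.OYSTER: (1_347_000.0, 14_060_000.0),
    SpeciesGroup.MUSSEL: (1_288_000.0, 4_850_000.0),
}


@dataclass(frozen=True)
class HarvestRecord:
    """One species group in one action area: biomass, price, revenue."""

    species_group: SpeciesGroup
    action_area: str
    area_km2: float
    harvest_kg: float
    price_usd_per_kg: float
    revenue_usd: float

    def __post_init__(self) -> None:
        for field_name in ("area_km2", "harvest_kg", "price_usd_per_kg", "revenue_usd"):
            value = getattr(self, field_name)
            if not value >= 0.0:
                raise ValidationError(
                    f"{field_name} must be non-negative, got {value!r} "
                    f"({self.species_group.value}, {self.action_area})"
                )


@dataclass(frozen=True)
class SpeciesTotal:
    """Annual biomass and revenue total for one species group."""

    harvest_kg: float
    revenue_usd: float

    @property
    def avg_price_usd_per_kg(self) -> float:
        if self.harvest_kg == 0.0:
            raise ValidationError("average price undefined: zero total harvest")
        return self.revenue_usd / self.harvest_kg


@dataclass(frozen=True)
class GrandTotal:
    harvest_kg: float
    revenue_usd: float
    avg_price_usd_per_kg: float


class HarvestTable:
    """Ordered harvest records plus canonical per-species totals.

    If ``canonical_species_totals`` is omitted the totals are exact sums of the
    records (the synthetic-data path); the packaged baseline supplies published
    totals explicitly.
    """

    def __init__(
        self,
        records: Iterable[HarvestRecord],
        canonical_species_totals: Mapping[SpeciesGroup, tuple[float, float]] | None = None,
    ) -> None:
        self.records: list[HarvestRecord] = list(records)
        seen: set[tuple[SpeciesGroup, str]] = set()
        for rec in self.records:
            key = (rec.species_group, rec.action_area)
            if key in seen:
                raise ValidationError(
                    f"duplicate record for {rec.species_group.value} / {rec.action_area}"
                )
            seen.add(key)
        if canonical_species_totals is None:
            totals: dict[SpeciesGroup, SpeciesTotal] = {}
            for rec in self.records:
                prev = totals.get(rec.species_group, SpeciesTotal(0.0, 0.0))
                totals[rec.species_group] = SpeciesTotal(
                    prev.harvest_kg + rec.harvest_kg,
                    prev.revenue_usd + rec.revenue_usd,
                )
            self.species_totals = totals
        else:
            self.species_totals = {
                sp: SpeciesTotal(kg, usd) for sp, (kg, usd) in canonical_species_totals.items()
            }

    def __len__(self) -> int:
        return len(self.records)

    def species_total(self, species: SpeciesGroup) -> SpeciesTotal:
        try:
            return self.species_totals[species]
        except KeyError:
            raise ValidationError(f"no records or totals for species {species.value}") from None

    def grand_total(self) -> GrandTotal:
        """Sum of canonical species totals, plus the implied average price."""
        if not self.species_totals:
            raise ValidationError("grand total undefined for an empty table")
        harvest = sum(t.harvest_kg for t in self.species_totals.values())
        revenue = sum(t.revenue_usd for t in self.species_totals.values())
        if harvest == 0.0:
            raise ValidationError("average price undefined: zero total harvest")
        return GrandTotal(harvest, revenue, revenue / harvest)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species_group": rec.species_group.value,
                    "action_area": rec.action_area,
                    "area_km2": rec.area_km2,
                    "harvest_kg": rec.harvest_kg,
                    "price_usd_per_kg": rec.price_usd_per_kg,
                    "revenue_usd": rec.revenue_usd,
                }
                for rec in self.records
            ],
            columns=list(REQUIRED_COLUMNS),
        )


def _records_from_frame(df: pd.DataFrame, source: str) -> list[HarvestRecord]:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing column(s) {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        try:
            species = SpeciesGroup(str(row.species_group))
        except ValueError:
            raise ValidationError(
                f"{source}: unknown species_group {row.species_group!r}"
            ) from None
        try:
            numeric = {
                "area_km2": float(row.area_km2),
                "harvest_kg": float(row.harvest_kg),
                "price_usd_per_kg": float(row.price_usd_per_kg),
                "revenue_usd": float(row.revenue_usd),
            }
        except (TypeError, ValueError):
            raise FormatError(f"{source}: non-numeric value in row {row!r}") from None
        records.append(
            HarvestRecord(species_group=species, action_area=str(row.action_area), **numeric)
        )
    return records


def load_harvest_table(path: str | Path) -> HarvestTable:
    """Read a harvest table CSV (comma-delimited, ``#`` comment lines allowed)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    return HarvestTable(_records_from_frame(df, str(path)))


def write_harvest_table(table: HarvestTable, path: str | Path, header: str | None = None) -> None:
    """Write a table as CSV; numeric values round-trip exactly as decimal text."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        table.to_frame().to_csv(fh, index=False)


def packaged_baseline() -> HarvestTable:
    """The 2009 Puget Sound baseline with published canonical species totals."""
    ref = resources.files("crabrisk.data").joinpath("puget_sound_harvest_2009.csv")
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, comment="#")
    return HarvestTable(
        _records_from_frame(df, "packaged baseline"),
        canonical_species_totals=CANONICAL_SPECIES_TOTALS,
    )
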