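"""Benefit-transfer economic cascade for the Puget Sound shellfishery.

Secondary economic values (processing, distribution, labour income,
employment) are not published for Puget Sound shellfish, so they are
transferred from a documented reference economy — British Columbia's 2005
shellfishery — by assuming the same ratios of each secondary component to
harvesting (landed/farm-gate) value:

    processing   = ps_harvesting * (bc_processing / bc_harvesting)
    distribution = 0.15 * (harvesting + processing)
    labour       = bc_labour * scale,   employment = bc_employment * scale
    with scale   = ps_harvesting / bc_harvesting

Scenario revenue-loss fractions L scale harvesting, processing, labour and
employment by (1 - L); distribution is recomputed from the scaled components,
which preserves its identity and makes it scale by exactly (1 - L) too.
Monetary values are in millions of USD; employment in person-years (PYs),
kept at full precision internally and rounded only when reported. No currency
or inflation adjustment is applied — the transfer uses ratios directly.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import pandas as pd

from .config import package_defaults
from .errors import ValidationError

__all__ = [
    "BenefitTransferInputs",
    "EconomicCascade",
    "LossSummary",
    "default_benefit_transfer",
    "baseline_cascade",
    "apply_loss",
    "loss_summary",
    "cascade_report",
]


@dataclass(frozen=True)
class BenefitTransferInputs:
    """Reference-economy values (USD M and person-years) and the distribution rate."""

    bc_harvesting: float = 139.0
    bc_processing: float = 71.0
    bc_distribution: float = 32.0
    bc_labour: float = 95.0
    bc_employment: float = 2580.0
    distribution_rate: float = 0.15

    def __post_init__(self) -> None:
        for name in ("bc_harvesting", "bc_processing", "bc_distribution", "bc_labour", "bc_employment"):
            if not getattr(self, name) > 0.0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 < self.distribution_rate < 1.0:
            raise ValidationError("distribution_rate must lie in (0, 1)")


def default_benefit_transfer() -> BenefitTransferInputs:
    block = package_defaults()["benefit_transfer"]
    return BenefitTransferInputs(
        bc_harvesting=float(block["bc_harvesting_usd_m"]),
        bc_processing=float(block["bc_processing_usd_m"]),
        bc_distribution=float(block["bc_distribution_usd_m"]),
        bc_labour=float(block["bc_labour_usd_m"]),
        bc_employment=float(block["bc_employment_py"]),
        distribution_rate=float(block["distribution_rate"]),
    )


@dataclass(frozen=True)
class EconomicCascade:
    """One state of the fishery: primary value plus transferred secondary values.

    Monetary fields in USD M; employment in person-years (unrounded float).
    """

    harvesting: float
    processing: float
    distribution: float
    labour_income: float
    employment: float

    def __post_init__(self) -> None:
        for name in ("harvesting", "processing", "distribution", "labour_income", "employment"):
            if getattr(self, name) < 0.0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def employment_py(self) -> int:
        """Employment rounded to whole person-years, as reported."""
        return round(self.employment)


def baseline_cascade(
    ps_harvesting: float, bt: BenefitTransferInputs | None = None
) -> EconomicCascade:
    """Transfer the reference-economy ratios onto a harvesting value (USD M)."""
    bt = bt if bt is not None else BenefitTransferInputs()
    if not ps_harvesting > 0.0:
        raise ValidationError("ps_harvesting must be positive")
    scale = ps_harvesting / bt.bc_harvesting
    processing = bt.bc_processing * scale
    return EconomicCascade(
        harvesting=ps_harvesting,
        processing=processing,
        distribution=bt.distribution_rate * (ps_harvesting + processing),
        labour_income=bt.bc_labour * scale,
        employment=bt.bc_employment * scale,
    )


def apply_loss(
    base: EconomicCascade,
    loss_fraction: float,
    distribution_rate: float = 0.15,
) -> EconomicCascade:
    """Scale a cascade by a revenue loss fraction L in [0, 1].

    Harvesting, processing, labour and employment scale by (1 - L);
    distribution is recomputed as rate * (harvesting' + processing').
    """
    if not 0.0 <= loss_fraction <= 1.0:
        raise ValidationError(f"loss_fraction must lie in [0, 1], got {loss_fraction!r}")
    keep = 1.0 - loss_fraction
    harvesting = base.harvesting * keep
    processing = base.processing * keep
    return EconomicCascade(
        harvesting=harvesting,
        processing=processing,
        distribution=distribution_rate * (harvesting + processing),
        labour_income=base.labour_income * keep,
        employment=base.employment * keep,
    )


@dataclass(frozen=True)
class LossSummary:
    """Differences between a baseline cascade and a post-invasion cascade."""

    jobs_lost_py: int
    secondary_loss_usd_m: float
    harvesting_loss_usd_m: float
    processing_loss_usd_m: float
    distribution_loss_usd_m: float
    labour_loss_usd_m: float


def loss_summary(base: EconomicCascade, after: EconomicCascade) -> LossSummary:
    """Per-component losses; jobs lost in whole PYs, secondary loss is
    processing plus distribution."""
    deltas = {
        name: getattr(base, name) - getattr(after, name)
        for name in ("harvesting", "processing", "distribution", "labour_income", "employment")
    }
    if any(d < -1e-9 for d in deltas.values()):
        raise ValidationError("post-invasion cascade exceeds the baseline cascade")
    return LossSummary(
        jobs_lost_py=round(deltas["employment"]),
        secondary_loss_usd_m=deltas["processing"] + deltas["distribution"],
        harvesting_loss_usd_m=deltas["harvesting"],
        processing_loss_usd_m=deltas["processing"],
        distribution_loss_usd_m=deltas["distribution"],
        labour_loss_usd_m=deltas["labour_income"],
    )


def cascade_report(
    base: EconomicCascade,
    loss_fractions: Dict[Tuple[str, str], float],
    distribution_rate: float = 0.15,
) -> pd.DataFrame:
    """Projected-value table: components x (baseline + one column per cell).

    ``loss_fractions`` maps (calorie_level, density_level) -> revenue loss
    fraction. Rows are the cascade components; employment is reported rounded.
    """
    columns: Dict[str, EconomicCascade] = {"baseline": base}
    for (cal_level, den_level), frac in loss_fractions.items():
        columns[f"{cal_level}_cal/{den_level}_den"] = apply_loss(
            base, frac, distribution_rate
        )
    rows = {
        "harvesting_usd_m": {k: c.harvesting for k, c in columns.items()},
        "processing_usd_m": {k: c.processing for k, c in columns.items()},
        "distribution_usd_m": {k: c.distribution for k, c in columns.items()},
        "labour_income_usd_m": {k: c.labour_income for k, c in columns.items()},
        "employment_py": {k: c.employment_py for k, c in columns.items()},
    }
    return pd.DataFrame(rows).T[list(columns)]
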