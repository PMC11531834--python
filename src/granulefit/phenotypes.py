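"""Scalar phenotypes per sample and per plant.

Covers the count-based phenotypes (granules per mg of grain, percentage of
small granules by number) and aggregation of grain-level mixture-fit
phenotypes to plant level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .distributions import BinnedDistribution, SamplePrep, ValueKind, Weighting
from .errors import ContractError

__all__ = [
    "PhenotypeRecord",
    "granules_per_mg",
    "pct_small",
    "summarize_plant",
    "DEFAULT_SMALL_THRESHOLD_UM",
]

DEFAULT_SMALL_THRESHOLD_UM = 10.0

#: Grain-level fields averaged when summarizing a plant.
AGGREGATED_FIELDS = (
    "granules_per_mg", "pct_small_by_number", "b_volume_percent",
    "mean_diam_A_um", "mean_diam_B_um", "median_diam_A_um", "median_diam_B_um",
)


@dataclass(frozen=True)
class PhenotypeRecord:
    """Per-plant phenotype summary (mean over that plant's grains)."""

    plant_id: str
    genotype: str
    dpa: Optional[float] = None
    granules_per_mg: Optional[float] = None
    pct_small_by_number: Optional[float] = None
    b_volume_percent: Optional[float] = None
    mean_diam_A_um: Optional[float] = None
    mean_diam_B_um: Optional[float] = None
    median_diam_A_um: Optional[float] = None
    median_diam_B_um: Optional[float] = None
    n_grains_averaged: int = 1

    def __post_init__(self) -> None:
        for name in ("pct_small_by_number", "b_volume_percent"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.granules_per_mg is not None and self.granules_per_mg < 0:
            raise ValueError("granules_per_mg must be >= 0")
        if self.n_grains_averaged < 1:
            raise ValueError("n_grains_averaged must be >= 1")


def granules_per_mg(prep: SamplePrep) -> float:
    """Back-calculate granule count per mg grain from the dilution scheme.

    counted · (total volume / aliquot volume) / grain mass.
    """
    dilution = prep.total_volume_mL / prep.aliquot_volume_mL
    return prep.counted_granules * dilution / prep.grain_mass_mg


def pct_small(dist: BinnedDistribution,
              threshold: float = DEFAULT_SMALL_THRESHOLD_UM) -> float:
    """Percentage of granules (by number) with diameter below ``threshold``.

    The inequality is strict.  A bin straddling the threshold contributes
    the fraction of its width below the threshold on the log scale
    (mass assumed uniform in ln d within a bin, consistent with log binning).
    """
    if dist.weighting is not Weighting.NUMBER:
        raise ContractError(
            "pct_small requires a number-weighted distribution; "
            "use convert_weighting first")
    if dist.value_kind not in (ValueKind.COUNT, ValueKind.PERCENT):
        raise ContractError(
            f"pct_small requires count or percent values, got "
            f"{dist.value_kind.value}")
    edges = dist.bin_edges
    values = dist.values
    total = values.sum()
    if total <= 0:
        raise ContractError("distribution has no mass")
    if threshold <= edges[0]:
        return 0.0
    if threshold >= edges[-1]:
        return 100.0
    below = 0.0
    for lo, hi, v in zip(edges[:-1], edges[1:], values):
        if hi <= threshold:
            below += v
        elif lo < threshold:
            below += v * math.log(threshold / lo) / math.log(hi / lo)
    return 100.0 * below / total


def summarize_plant(grain_records: Sequence[Mapping],
                    plant_id: str,
                    genotype: str,
                    dpa: Optional[float] = None) -> Optional[PhenotypeRecord]:
    """Mean of grain-level phenotype mappings for one plant.

    Records flagged ``converged=False`` are excluded from the average; if no
    usable grain remains, returns ``None`` (caller logs the exclusion).
    Fields missing from every usable record stay ``None``.
    """
    usable = [r for r in grain_records if r.get("converged", True)]
    if not usable:
        return None
    agg = {}
    for name in AGGREGATED_FIELDS:
        vals = [r[name] for r in usable
                if r.get(name) is not None and not _isnan(r.get(name))]
        agg[name] = float(np.mean(vals)) if vals else None
    return PhenotypeRecord(plant_id=str(plant_id), genotype=str(genotype),
                           dpa=dpa, n_grains_averaged=len(usable), **agg)


def _isnan(v) -> bool:
    try:
        return math.isnan(float(v))
    except (TypeError, ValueError):
        return False
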