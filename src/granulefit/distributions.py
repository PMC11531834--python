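"""Binned granule-size distributions and the binning/weighting transforms.

The central value type is :class:`BinnedDistribution`: per-bin magnitudes over
strictly increasing diameter bin edges (µm), tagged with a *weighting*
(number- or volume-weighted) and a *value kind* (raw counts, percentages, or
percentage density = percent / bin width).  Instances are immutable; every
transform returns a new object.

Representative bin diameter is the geometric mean of the bin's edges
throughout — bins are logarithmic, and an arithmetic midpoint biases any
d³ (volume) weighting.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Optional, Sequence

import numpy as np

from .errors import ContractError, EmptyDistributionError

__all__ = [
    "Weighting",
    "ValueKind",
    "BinnedDistribution",
    "GranulePopulation",
    "SamplePrep",
    "make_log_edges",
    "to_density",
    "from_density",
    "counts_to_percent",
    "convert_weighting",
    "bin_population",
    "average_distributions",
    "sphere_volume",
    "DEFAULT_WINDOW_UM",
]

#: Default instrument measurement window, µm.  A 70 µm aperture resolves
#: particles between 2% and 60% of its diameter.
DEFAULT_WINDOW_UM = (1.4, 42.0)

_NORM_RTOL = 1e-6


class Weighting(str, enum.Enum):
    NUMBER = "number"
    VOLUME = "volume"


class ValueKind(str, enum.Enum):
    COUNT = "count"
    PERCENT = "percent"
    PERCENT_DENSITY = "percent_density"


def sphere_volume(diameter: np.ndarray | float) -> np.ndarray | float:
    """Volume of a sphere of the given equivalent spherical diameter."""
    return (np.pi / 6.0) * np.asarray(diameter, dtype=float) ** 3


def _frozen(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float).copy()
    a.setflags(write=False)
    return a


@dataclass(frozen=True)
class BinnedDistribution:
    """Diameter-binned particle data with explicit weighting and value kind.

    Parameters
    ----------
    bin_edges : array-like, shape (n+1,)
        Strictly increasing, all-positive diameters in µm.
    values : array-like, shape (n,)
        Per-bin magnitudes, all finite and ≥ 0.
    weighting : Weighting
        Whether magnitudes are number- or volume-weighted.
    value_kind : ValueKind
        count, percent (Σ = 100) or percent_density (∫ = 100).
    meta : mapping
        Free-form sample annotations (sample_id, genotype, plant, dpa, ...).
    """

    bin_edges: np.ndarray
    values: np.ndarray
    weighting: Weighting
    value_kind: ValueKind
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        edges = _frozen(self.bin_edges)
        values = _frozen(self.values)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "weighting", Weighting(self.weighting))
        object.__setattr__(self, "value_kind", ValueKind(self.value_kind))
        object.__setattr__(self, "meta", dict(self.meta))
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("bin_edges must be 1-D with at least two entries")
        if not np.all(edges > 0):
            raise ValueError("bin_edges must all be > 0")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin_edges must be strictly increasing")
        if values.shape != (edges.size - 1,):
            raise ValueError(
                f"values has length {values.size}, expected {edges.size - 1}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if np.any(values < 0):
            raise ValueError("values must be >= 0")
        if self.value_kind is ValueKind.PERCENT:
            total = float(values.sum())
            if not math.isclose(total, 100.0, rel_tol=_NORM_RTOL):
                raise ValueError(f"percent values sum to {total}, expected 100")
        elif self.value_kind is ValueKind.PERCENT_DENSITY:
            total = float((values * np.diff(edges)).sum())
            if not math.isclose(total, 100.0, rel_tol=_NORM_RTOL):
                raise ValueError(
                    f"percent_density integrates to {total}, expected 100"
                )

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def centers(self) -> np.ndarray:
        """Geometric-mean diameter of each bin."""
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    def with_meta(self, **extra: Any) -> "BinnedDistribution":
        meta = dict(self.meta)
        meta.update(extra)
        return replace(self, meta=meta)


@dataclass(frozen=True)
class GranulePopulation:
    """A set of individual granules given by equivalent spherical diameter.

    ``labels`` optionally tags each granule as belonging to the A or B
    component (simulator ground truth; real instruments cannot label).
    """

    diameters: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        d = _frozen(self.diameters)
        object.__setattr__(self, "diameters", d)
        if d.ndim != 1:
            raise ValueError("diameters must be 1-D")
        if d.size and not np.all(d > 0):
            raise ValueError("diameters must all be > 0")
        if self.labels is not None:
            labels = np.asarray(self.labels)
            labels.setflags(write=False)
            object.__setattr__(self, "labels", labels)
            if labels.shape != d.shape:
                raise ValueError("labels must match diameters in length")

    def __len__(self) -> int:
        return self.diameters.size


@dataclass(frozen=True)
class SamplePrep:
    """Dilution scheme of one volumetric run, for count back-calculation."""

    aliquot_volume_mL: float
    total_volume_mL: float
    grain_mass_mg: float
    counted_granules: int

    def __post_init__(self) -> None:
        if self.aliquot_volume_mL <= 0 or self.total_volume_mL <= 0:
            raise ValueError("volumes must be > 0")
        if self.aliquot_volume_mL > self.total_volume_mL:
            raise ValueError("aliquot volume cannot exceed total volume")
        if self.grain_mass_mg <= 0:
            raise ValueError("grain mass must be > 0")
        if self.counted_granules < 0:
            raise ValueError("counted_granules must be >= 0")


def make_log_edges(d_min: float, d_max: float, n_bins: int) -> np.ndarray:
    """Geometrically spaced bin edges: edge[i+1]/edge[i] constant.

    Mirrors instrument-style logarithmic diameter binning.
    """
    if not (0 < d_min < d_max):
        raise ValueError(f"need 0 < d_min < d_max, got [{d_min}, {d_max}]")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.geomspace(d_min, d_max, n_bins + 1)
    edges[0] = d_min  # pin endpoints exactly
    edges[-1] = d_max
    return edges


def to_density(dist: BinnedDistribution) -> BinnedDistribution:
    """percent → percent_density: divide each bin value by its width.

    This is the even-bin transform: after it, distributions recorded on
    logarithmic bins can be compared and fitted on a linear diameter axis.
    """
    if dist.value_kind is not ValueKind.PERCENT:
        raise ContractError(
            f"to_density requires value_kind=percent, got {dist.value_kind.value}"
        )
    return replace(dist, values=dist.values / dist.widths,
                   value_kind=ValueKind.PERCENT_DENSITY)


def from_density(dist: BinnedDistribution) -> BinnedDistribution:
    """Inverse of :func:`to_density`."""
    if dist.value_kind is not ValueKind.PERCENT_DENSITY:
        raise ContractError(
            "from_density requires value_kind=percent_density, "
            f"got {dist.value_kind.value}"
        )
    return replace(dist, values=dist.values * dist.widths,
                   value_kind=ValueKind.PERCENT)


def counts_to_percent(dist: BinnedDistribution) -> BinnedDistribution:
    """count → percent (values rescaled to sum to 100)."""
    if dist.value_kind is not ValueKind.COUNT:
        raise ContractError(
            f"counts_to_percent requires value_kind=count, got {dist.value_kind.value}"
        )
    total = dist.values.sum()
    if total <= 0:
        raise EmptyDistributionError("all-zero counts")
    return replace(dist, values=100.0 * dist.values / total,
                   value_kind=ValueKind.PERCENT)


def convert_weighting(dist: BinnedDistribution, target: Weighting | str
                      ) -> BinnedDistribution:
    """Re-weight a binned distribution between number and volume.

    Each bin is scaled by the representative sphere volume (π/6)·d_c³ with
    d_c the geometric mean of the bin's edges (number → volume multiplies,
    volume → number divides), then renormalized when the value kind is
    percent.  Applying the operation twice with opposite targets recovers
    the input to floating-point accuracy.
    """
    target = Weighting(target)
    if target is dist.weighting:
        return dist
    if dist.value_kind is ValueKind.PERCENT_DENSITY:
        raise ContractError(
            "convert_weighting does not accept percent_density; convert "
            "before densifying"
        )
    vol = sphere_volume(dist.centers)
    if target is Weighting.VOLUME:
        values = dist.values * vol
    else:
        values = dist.values / vol
    if dist.value_kind is ValueKind.PERCENT:
        values = 100.0 * values / values.sum()
    return replace(dist, values=values, weighting=target)


def bin_population(pop: GranulePopulation,
                   edges: Sequence[float] | np.ndarray,
                   weighting: Weighting | str,
                   value_kind: ValueKind | str | None = None,
                   ) -> BinnedDistribution:
    """Bin a granule population onto explicit edges.

    Number weighting yields per-bin granule counts (value kind ``count`` by
    default); volume weighting yields the per-bin share of total sphere
    volume as percent.  Bins are half-open [low, high) with the last bin
    closed.  Granules outside the edge range are never silently dropped:
    they are tallied in the returned distribution's ``meta`` under
    ``overflow`` (counts and volumes below/above the window).
    """
    weighting = Weighting(weighting)
    edges = np.asarray(edges, dtype=float)
    if len(pop) == 0:
        raise EmptyDistributionError("empty population")
    d = pop.diameters
    below = d < edges[0]
    above = d > edges[-1]
    inside = ~(below | above)
    overflow = {
        "n_below": int(below.sum()),
        "n_above": int(above.sum()),
        "volume_below": float(sphere_volume(d[below]).sum()),
        "volume_above": float(sphere_volume(d[above]).sum()),
    }
    if not inside.any():
        raise EmptyDistributionError("no granules inside the bin range")
    d_in = d[inside]
    if weighting is Weighting.NUMBER:
        counts, _ = np.histogram(d_in, bins=edges)
        values = counts.astype(float)
        kind = ValueKind.COUNT if value_kind is None else ValueKind(value_kind)
        if kind is ValueKind.PERCENT:
            values = 100.0 * values / values.sum()
    else:
        vols, _ = np.histogram(d_in, bins=edges, weights=sphere_volume(d_in))
        kind = ValueKind.PERCENT if value_kind is None else ValueKind(value_kind)
        if kind is ValueKind.PERCENT:
            values = 100.0 * vols / vols.sum()
        elif kind is ValueKind.COUNT:
            values = vols  # raw per-bin volume sums, µm³
        else:
            raise ContractError("bin_population cannot emit percent_density directly")
    return BinnedDistribution(edges, values, weighting, kind,
                              meta={"overflow": overflow})


def average_distributions(dists: Sequence[BinnedDistribution]
                          ) -> BinnedDistribution:
    """Arithmetic mean trace of same-binned, same-kind distributions."""
    if not dists:
        raise EmptyDistributionError("no distributions to average")
    first = dists[0]
    for d in dists[1:]:
        if not np.allclose(d.bin_edges, first.bin_edges):
            raise ContractError("distributions have different bin edges")
        if d.value_kind is not first.value_kind or d.weighting is not first.weighting:
            raise ContractError("distributions have mixed kinds/weightings")
    mean = np.mean([d.values for d in dists], axis=0)
    if first.value_kind is ValueKind.PERCENT:
        mean = 100.0 * mean / mean.sum()
    return BinnedDistribution(first.bin_edges, mean, first.weighting,
                              first.value_kind,
                              meta={"n_averaged": len(dists)})
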