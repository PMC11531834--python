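"""Synthetic granule populations, measurements and whole mock experiments.

Populations are two-component log-normal mixtures of equivalent spherical
diameters.  The mixing fraction can be specified on either the number or the
volume scale; the two are linked in closed form through the components'
third moments, since a granule's volume scales with d³:

    m3 = median³ · exp(4.5 · sdlog²)          (third moment of a log-normal)
    f_number = (f_volume/m3_B) / (f_volume/m3_B + (1−f_volume)/m3_A)

Measurement emulation truncates to the instrument window, bins on log edges
and reports per-bin volume percent, with optional multinomial subsampling for
counting noise.  ``simulate_experiment`` writes complete mock datasets
(traces + sample sheet + generating-truth table) in the package's CSV
formats; every output is a deterministic function of (design, base seed).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .distributions import (DEFAULT_WINDOW_UM, BinnedDistribution,
                            GranulePopulation, ValueKind, Weighting,
                            bin_population, make_log_edges, sphere_volume)
from .errors import EmptyDistributionError
from .io import SampleSheet, write_sample_sheet, write_trace

__all__ = [
    "SimSpec",
    "ExperimentDesign",
    "SimulatedExperiment",
    "number_fraction_from_volume_fraction",
    "volume_fraction_from_number_fraction",
    "simulate_population",
    "simulate_measurement",
    "simulate_experiment",
    "default_panel_design",
    "default_timecourse_design",
]

DEFAULT_N_BINS = 256


def _lognormal_m3(median: float, sdlog: float) -> float:
    """Third raw moment of a log-normal with the given median and sdlog."""
    return median ** 3 * math.exp(4.5 * sdlog ** 2)


def number_fraction_from_volume_fraction(f_volume: float,
                                         median_a: float, sdlog_a: float,
                                         median_b: float, sdlog_b: float
                                         ) -> float:
    """B-component number fraction implied by its volume fraction."""
    if not 0.0 <= f_volume <= 1.0:
        raise ValueError("volume fraction must be in [0, 1]")
    m3_a = _lognormal_m3(median_a, sdlog_a)
    m3_b = _lognormal_m3(median_b, sdlog_b)
    num = f_volume / m3_b
    return num / (num + (1.0 - f_volume) / m3_a)


def volume_fraction_from_number_fraction(f_number: float,
                                         median_a: float, sdlog_a: float,
                                         median_b: float, sdlog_b: float
                                         ) -> float:
    """Inverse of :func:`number_fraction_from_volume_fraction`."""
    if not 0.0 <= f_number <= 1.0:
        raise ValueError("number fraction must be in [0, 1]")
    m3_a = _lognormal_m3(median_a, sdlog_a)
    m3_b = _lognormal_m3(median_b, sdlog_b)
    num = f_number * m3_b
    return num / (num + (1.0 - f_number) * m3_a)


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic measurement.

    Exactly one of ``f_b_volume`` / ``f_b_number`` must be given; the other
    is derived via the third-moment closed form.
    """

    n_granules: int
    median_diam_a_um: float = 22.0
    sdlog_a: float = 0.25
    median_diam_b_um: float = 5.0
    sdlog_b: float = 0.30
    f_b_volume: Optional[float] = None
    f_b_number: Optional[float] = None
    seed: int = 0
    window_um: Tuple[float, float] = DEFAULT_WINDOW_UM
    n_bins: int = DEFAULT_N_BINS

    def __post_init__(self) -> None:
        if self.n_granules <= 0:
            raise ValueError("n_granules must be > 0")
        if self.median_diam_a_um <= 0 or self.median_diam_b_um <= 0:
            raise ValueError("median diameters must be > 0")
        if self.sdlog_a <= 0 or self.sdlog_b <= 0:
            raise ValueError("sdlogs must be > 0")
        if (self.f_b_volume is None) == (self.f_b_number is None):
            raise ValueError(
                "exactly one of f_b_volume / f_b_number must be set")
        f = self.f_b_volume if self.f_b_volume is not None else self.f_b_number
        if not 0.0 <= f <= 1.0:
            raise ValueError("mixing fraction must be in [0, 1]")

    @property
    def resolved_f_b_number(self) -> float:
        if self.f_b_number is not None:
            return self.f_b_number
        return number_fraction_from_volume_fraction(
            self.f_b_volume, self.median_diam_a_um, self.sdlog_a,
            self.median_diam_b_um, self.sdlog_b)

    @property
    def resolved_f_b_volume(self) -> float:
        if self.f_b_volume is not None:
            return self.f_b_volume
        return volume_fraction_from_number_fraction(
            self.f_b_number, self.median_diam_a_um, self.sdlog_a,
            self.median_diam_b_um, self.sdlog_b)

    # Volumetric traces are fitted with components describing the
    # volume-weighted diameter distribution; d³-weighting a log-normal
    # (mu, sigma) gives another log-normal at (mu + 3·sigma², sigma), so the
    # medians recoverable from a volumetric fit are the ones below.
    @property
    def volume_median_diam_a_um(self) -> float:
        return self.median_diam_a_um * math.exp(3.0 * self.sdlog_a ** 2)

    @property
    def volume_median_diam_b_um(self) -> float:
        return self.median_diam_b_um * math.exp(3.0 * self.sdlog_b ** 2)


def simulate_population(spec: SimSpec) -> GranulePopulation:
    """Draw a labeled granule population; bit-reproducible given the seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_granules
    is_b = rng.random(n) < spec.resolved_f_b_number
    z = rng.standard_normal(n)
    mu = np.where(is_b, math.log(spec.median_diam_b_um),
                  math.log(spec.median_diam_a_um))
    sdlog = np.where(is_b, spec.sdlog_b, spec.sdlog_a)
    diameters = np.exp(mu + sdlog * z)
    labels = np.where(is_b, "B", "A")
    return GranulePopulation(diameters=diameters, labels=labels)


def simulate_measurement(pop: GranulePopulation, spec: SimSpec,
                         subsample: Optional[int] = None,
                         rng: Optional[np.random.Generator] = None
                         ) -> BinnedDistribution:
    """Emulate one volumetric run on the population.

    Diameters outside the measurement window are truncated before binning
    (the instrument cannot see them); the truncated count and volume are
    reported in the output metadata.  With ``subsample``, per-bin counts are
    redrawn multinomially to emulate counting a smaller aliquot.
    """
    if len(pop) == 0:
        raise EmptyDistributionError("empty population")
    edges = make_log_edges(*spec.window_um, spec.n_bins)
    dist = bin_population(pop, edges, Weighting.VOLUME)  # raises if all outside
    counts = bin_population(pop, edges, Weighting.NUMBER)
    meta = dict(dist.meta)
    meta["counted_granules"] = int(counts.values.sum())
    if subsample is not None:
        if rng is None:
            rng = np.random.default_rng(spec.seed + 1)
        c = counts.values
        sub = rng.multinomial(subsample, c / c.sum()).astype(float)
        vols = sub * sphere_volume(counts.centers)
        values = 100.0 * vols / vols.sum()
        meta["counted_granules"] = int(subsample)
        return BinnedDistribution(edges, values, Weighting.VOLUME,
                                  ValueKind.PERCENT, meta=meta)
    return BinnedDistribution(edges, dist.values, Weighting.VOLUME,
                              ValueKind.PERCENT, meta=meta)


# -- whole-experiment designs -------------------------------------------------

@dataclass(frozen=True)
class ExperimentDesign:
    """Genotypes × plants × grains (× dpa) with per-cell parameter overrides.

    ``cell_params`` maps genotype (no time course) or (genotype, dpa) to the
    SimSpec field overrides for that cell; missing cells use ``base`` values.
    ``plant_sd`` scales deterministic plant-to-plant variation (relative sd
    applied to the mixing fraction and both median diameters).
    """

    genotypes: Tuple[str, ...]
    n_plants: int
    n_grains: int
    dpa: Optional[Tuple[float, ...]] = None
    n_granules: int = 100_000
    cell_params: Mapping = field(default_factory=dict)
    base: Mapping = field(default_factory=dict)
    plant_sd: float = 0.08
    window_um: Tuple[float, float] = DEFAULT_WINDOW_UM
    n_bins: int = DEFAULT_N_BINS

    def __post_init__(self) -> None:
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ValueError("duplicate genotype labels")
        if self.n_plants < 1 or self.n_grains < 1:
            raise ValueError("need at least one plant and one grain")
        if self.dpa is not None and len(set(self.dpa)) != len(self.dpa):
            raise ValueError("duplicate dpa values")


@dataclass(frozen=True)
class SimulatedExperiment:
    out_dir: Path
    sheet_path: Path
    truth_path: Path
    sheet: SampleSheet
    truth: pd.DataFrame


def default_panel_design(n_plants: int = 9, n_grains: int = 3,
                         n_granules: int = 100_000) -> ExperimentDesign:
    """Two-genotype panel: mutant with more B volume and smaller A granules."""
    return ExperimentDesign(
        genotypes=("WT", "mutant"), n_plants=n_plants, n_grains=n_grains,
        n_granules=n_granules,
        cell_params={
            "WT": {"f_b_volume": 0.20, "median_diam_a_um": 22.0,
                   "median_diam_b_um": 5.0},
            "mutant": {"f_b_volume": 0.35, "median_diam_a_um": 19.5,
                       "median_diam_b_um": 5.5},
        })


def default_timecourse_design(n_plants: int = 4, n_grains: int = 1,
                              n_granules: int = 100_000) -> ExperimentDesign:
    """Developmental series: B mode absent early, appearing earlier in the
    mutant (14 dpa) than in the wild type (20 dpa), with slower A growth in
    the mutant at later time points."""
    cells = {
        ("WT", 8): {"f_b_volume": 0.0, "median_diam_a_um": 10.0},
        ("WT", 14): {"f_b_volume": 0.0, "median_diam_a_um": 17.0},
        ("WT", 20): {"f_b_volume": 0.15, "median_diam_a_um": 20.0,
                     "median_diam_b_um": 4.0},
        ("WT", 30): {"f_b_volume": 0.25, "median_diam_a_um": 22.0,
                     "median_diam_b_um": 5.0},
        ("mutant", 8): {"f_b_volume": 0.0, "median_diam_a_um": 10.0},
        ("mutant", 14): {"f_b_volume": 0.12, "median_diam_a_um": 15.0,
                         "median_diam_b_um": 4.0},
        ("mutant", 20): {"f_b_volume": 0.25, "median_diam_a_um": 17.0,
                         "median_diam_b_um": 4.5},
        ("mutant", 30): {"f_b_volume": 0.35, "median_diam_a_um": 19.0,
                         "median_diam_b_um": 5.5},
    }
    return ExperimentDesign(genotypes=("WT", "mutant"), n_plants=n_plants,
                            n_grains=n_grains, dpa=(8, 14, 20, 30),
                            n_granules=n_granules, cell_params=cells)


def _derive_seed(*parts) -> int:
    """Stable 63-bit seed from hashed identity parts.

    Hashing (base_seed, genotype, plant, grain, dpa) means adding samples to
    a design never perturbs existing ones.
    """
    key = "|".join(str(p) for p in parts).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:8], "big") >> 1


def _cell_spec(design: ExperimentDesign, genotype: str,
               dpa: Optional[float]) -> Dict:
    params = {"f_b_volume": 0.2}
    params.update(design.base)
    key = genotype if design.dpa is None else (genotype, dpa)
    params.update(design.cell_params.get(key, {}))
    return params


def _jitter_params(params: Dict, rng: np.random.Generator, sd: float) -> Dict:
    """Deterministic plant-level variation around the cell parameters."""
    out = dict(params)
    for name in ("median_diam_a_um", "median_diam_b_um"):
        base = out.get(name, SimSpec.__dataclass_fields__[name].default)
        out[name] = base * math.exp(sd * 0.4 * rng.standard_normal())
    for name in ("f_b_volume", "f_b_number"):
        if out.get(name):
            out[name] = min(max(
                out[name] * math.exp(sd * rng.standard_normal()), 0.0), 1.0)
    return out


def simulate_experiment(design: ExperimentDesign, out_dir,
                        base_seed: int = 0) -> SimulatedExperiment:
    """Write a full mock dataset: traces, sample sheet and truth table."""
    out_dir = Path(out_dir)
    traces_dir = out_dir / "traces"
    traces_dir.mkdir(parents=True, exist_ok=True)
    dpa_levels: Tuple[Optional[float], ...] = (
        design.dpa if design.dpa is not None else (None,))

    sheet_rows = []
    truth_rows = []
    for genotype in design.genotypes:
        for dpa in dpa_levels:
            cell = _cell_spec(design, genotype, dpa)
            for plant in range(1, design.n_plants + 1):
                plant_rng = np.random.default_rng(
                    _derive_seed(base_seed, genotype, plant, dpa, "plant"))
                params = _jitter_params(cell, plant_rng, design.plant_sd)
                for grain in range(1, design.n_grains + 1):
                    seed = _derive_seed(base_seed, genotype, plant, grain, dpa)
                    spec = SimSpec(n_granules=design.n_granules, seed=seed,
                                   window_um=design.window_um,
                                   n_bins=design.n_bins, **params)
                    sample_id = f"{genotype}_p{plant:02d}_g{grain}"
                    if dpa is not None:
                        sample_id += f"_d{dpa:g}"
                    pop = simulate_population(spec)
                    meas = simulate_measurement(pop, spec)
                    meta = {"sample_id": sample_id, "genotype": genotype,
                            "plant": f"{genotype}_p{plant:02d}"}
                    if dpa is not None:
                        meta["dpa"] = dpa
                    meas = meas.with_meta(**meta)
                    trace_path = traces_dir / f"{sample_id}.csv"
                    write_trace(meas, trace_path)
                    grain_mass = 40.0 + 20.0 * np.random.default_rng(
                        seed + 7).random()
                    sheet_rows.append({
                        "sample_id": sample_id, "genotype": genotype,
                        "plant": f"{genotype}_p{plant:02d}",
                        "dpa": dpa if dpa is not None else np.nan,
                        "grain_mass_mg": round(grain_mass, 3),
                        "aliquot_volume_mL": 1.0, "total_volume_mL": 100.0,
                        "counted_granules": meas.meta["counted_granules"],
                        "trace_path": str(Path("traces") / f"{sample_id}.csv"),
                    })
                    truth_rows.append({
                        "sample_id": sample_id, "genotype": genotype,
                        "plant": f"{genotype}_p{plant:02d}",
                        "dpa": dpa if dpa is not None else np.nan,
                        "n_granules": spec.n_granules, "seed": seed,
                        "median_diam_a_um": spec.median_diam_a_um,
                        "sdlog_a": spec.sdlog_a,
                        "median_diam_b_um": spec.median_diam_b_um,
                        "sdlog_b": spec.sdlog_b,
                        "f_b_volume": spec.resolved_f_b_volume,
                        "f_b_number": spec.resolved_f_b_number,
                        "volume_median_diam_a_um": spec.volume_median_diam_a_um,
                        "volume_median_diam_b_um": spec.volume_median_diam_b_um,
                        "window_low_um": spec.window_um[0],
                        "window_high_um": spec.window_um[1],
                        "n_bins": spec.n_bins,
                    })
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    truth = pd.DataFrame(truth_rows)
    sheet_path = out_dir / "sample_sheet.csv"
    truth_path = out_dir / "truth.csv"
    write_sample_sheet(sheet, sheet_path)
    truth.to_csv(truth_path, index=False, lineterminator="\n",
                 float_format="%.12g")
    return SimulatedExperiment(out_dir=out_dir, sheet_path=sheet_path,
                               truth_path=truth_path, sheet=sheet, truth=truth)
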