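"""Two-component log-normal deconvolution of volumetric size distributions.

The model is a mixture of two Gaussians on the ln(diameter) axis —
equivalently two log-normal components in diameter — with the mixing weight
``f_b`` expressed on the *volume* scale, because the traces being fitted are
volume-percentage densities.  Component A is, by labeling convention, the
larger-diameter component (``exp(mu_a) > exp(mu_b)``); labels are assigned
after optimization, never constrained during it.

Fitting minimizes the unweighted sum of squared residuals between the
observed percent-density trace and the model density evaluated at each bin's
geometric-mean diameter, with box bounds on all parameters.  A Poisson-style
variance-stabilized objective is available as an alternative
(``objective="poisson"``).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import optimize, stats

from .distributions import (BinnedDistribution, ValueKind, Weighting,
                            counts_to_percent, to_density)
from .errors import ContractError, InsufficientDataError, UnconvergedFitError

__all__ = [
    "MixtureModel",
    "FitOptions",
    "FitResult",
    "Modality",
    "model_density",
    "single_density",
    "init_params",
    "fit_bimodal",
    "fit_unimodal",
    "extract_phenotypes",
    "classify_modality",
]

# Box bounds: exp(mu) in [1.5, 50] µm, sigma in [0.05, 1.0], f_b in [0, 1].
MU_BOUNDS = (math.log(1.5), math.log(50.0))
SIGMA_BOUNDS = (0.05, 1.0)
FB_BOUNDS = (0.0, 1.0)

_PARAM_NAMES = ("f_b", "mu_a", "sigma_a", "mu_b", "sigma_b")


@dataclass(frozen=True)
class MixtureModel:
    """Two log-normal components in diameter; mixing on the volume scale.

    ``f_b`` is the B-component fraction of total volume in [0, 1];
    ``mu_*``/``sigma_*`` are the mean and sd of ln(diameter/µm) of each
    component.
    """

    f_b: float
    mu_a: float
    sigma_a: float
    mu_b: float
    sigma_b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_b <= 1.0:
            raise ValueError("f_b must be in [0, 1]")
        if self.sigma_a <= 0 or self.sigma_b <= 0:
            raise ValueError("sigmas must be > 0")

    @property
    def median_diam_a(self) -> float:
        return math.exp(self.mu_a)

    @property
    def median_diam_b(self) -> float:
        return math.exp(self.mu_b)

    @property
    def mean_diam_a(self) -> float:
        """Arithmetic mean diameter of the fitted A component."""
        return math.exp(self.mu_a + self.sigma_a ** 2 / 2)

    @property
    def mean_diam_b(self) -> float:
        return math.exp(self.mu_b + self.sigma_b ** 2 / 2)

    def relabeled(self) -> "MixtureModel":
        """Enforce the convention exp(mu_a) > exp(mu_b) by swapping."""
        if self.mu_a >= self.mu_b:
            return self
        return MixtureModel(f_b=1.0 - self.f_b, mu_a=self.mu_b,
                            sigma_a=self.sigma_b, mu_b=self.mu_a,
                            sigma_b=self.sigma_a)


def single_density(mu: float, sigma: float, d) -> np.ndarray:
    """Percent-density of a single log-normal component (integrates to 100)."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be > 0")
    return 100.0 * stats.lognorm.pdf(d, s=sigma, scale=math.exp(mu))


def model_density(model: MixtureModel, d) -> np.ndarray:
    """Mixture percent-density at diameter d (µm); integrates to 100."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be > 0")
    pdf_a = stats.lognorm.pdf(d, s=model.sigma_a, scale=math.exp(model.mu_a))
    pdf_b = stats.lognorm.pdf(d, s=model.sigma_b, scale=math.exp(model.mu_b))
    return 100.0 * (model.f_b * pdf_b + (1.0 - model.f_b) * pdf_a)


@dataclass(frozen=True)
class FitOptions:
    """Bounds, tolerances and objective for the bounded least-squares fit."""

    mu_bounds: Tuple[float, float] = MU_BOUNDS
    sigma_bounds: Tuple[float, float] = SIGMA_BOUNDS
    fb_bounds: Tuple[float, float] = FB_BOUNDS
    tol: float = 1e-10
    max_iter: int = 500
    objective: str = "lsq"  # "lsq" | "poisson"
    fallback_split_um: float = 10.0
    init: Optional[MixtureModel] = None


@dataclass(frozen=True)
class FitResult:
    """Fitted mixture plus diagnostics and derived phenotypes."""

    model: MixtureModel
    rss: float
    converged: bool
    n_iter: int
    boundary_flags: Tuple[str, ...] = ()

    @property
    def b_volume_percent(self) -> float:
        return 100.0 * self.model.f_b

    @property
    def mean_diam_a(self) -> float:
        return self.model.mean_diam_a

    @property
    def mean_diam_b(self) -> float:
        return self.model.mean_diam_b


def _as_density(dist: BinnedDistribution) -> BinnedDistribution:
    if dist.weighting is not Weighting.VOLUME:
        raise ContractError(
            "mixture fitting expects a volume-weighted trace; use "
            "convert_weighting first")
    if dist.value_kind is ValueKind.COUNT:
        dist = counts_to_percent(dist)
    if dist.value_kind is ValueKind.PERCENT:
        dist = to_density(dist)
    return dist


def init_params(dist: BinnedDistribution,
                options: FitOptions = FitOptions()) -> MixtureModel:
    """Deterministic initial guess from the shape of the density trace.

    Splits the diameter axis at the density minimum between the two largest
    well-separated local maxima; if the trace looks unimodal, falls back to a
    fixed split (default 10 µm).  Each side contributes log-moment estimates
    for (mu, sigma) and the B side's volume share seeds ``f_b``.
    """
    dist = _as_density(dist)
    y = dist.values
    if int((y > 0).sum()) < 6:
        raise InsufficientDataError(
            f"need >= 6 informative bins, got {int((y > 0).sum())}")
    d_c = dist.centers
    mass = y * dist.widths  # per-bin volume percent

    split = _find_split(d_c, y, options.fallback_split_um)
    b_side = d_c < split

    def side_moments(sel: np.ndarray, default_mu: float) -> Tuple[float, float]:
        w = mass[sel]
        if w.sum() <= 0:
            return default_mu, 0.3
        ln_d = np.log(d_c[sel])
        mu = float(np.average(ln_d, weights=w))
        var = float(np.average((ln_d - mu) ** 2, weights=w))
        sigma = math.sqrt(max(var, 1e-6))
        return mu, sigma

    mu_b, sigma_b = side_moments(b_side, math.log(split) - 0.7)
    mu_a, sigma_a = side_moments(~b_side, math.log(split) + 0.7)
    f_b = float(mass[b_side].sum() / mass.sum())

    lo_mu, hi_mu = options.mu_bounds
    lo_s, hi_s = options.sigma_bounds
    clip = lambda v, lo, hi: min(max(v, lo), hi)
    model = MixtureModel(
        f_b=clip(f_b, *options.fb_bounds),
        mu_a=clip(mu_a, lo_mu, hi_mu),
        sigma_a=clip(sigma_a, lo_s, hi_s),
        mu_b=clip(mu_b, lo_mu, hi_mu),
        sigma_b=clip(sigma_b, lo_s, hi_s),
    )
    return model.relabeled()


def _find_split(d_c: np.ndarray, y: np.ndarray, fallback: float) -> float:
    """Diameter separating the two candidate modes of a density trace."""
    from scipy.signal import find_peaks

    peaks, props = find_peaks(y, height=0.02 * y.max())
    if len(peaks) >= 2:
        order = np.argsort(props["peak_heights"])[::-1]
        for j in order[1:]:
            i, k = sorted((peaks[order[0]], peaks[j]))
            # well-separated: modes at least a factor 1.5 apart in diameter
            if d_c[k] / d_c[i] >= 1.5:
                valley = i + int(np.argmin(y[i:k + 1]))
                return float(d_c[valley])
    return float(fallback)


def _pack(m: MixtureModel) -> np.ndarray:
    return np.array([m.f_b, m.mu_a, m.sigma_a, m.mu_b, m.sigma_b])


def _unpack(theta: np.ndarray) -> MixtureModel:
    return MixtureModel(*theta)


def fit_bimodal(dist: BinnedDistribution,
                options: FitOptions = FitOptions()) -> FitResult:
    """Bounded nonlinear least squares of the 2-component mixture.

    Deterministic given (dist, options).  Non-convergence never raises: the
    returned :class:`FitResult` carries ``converged=False``.  Any parameter
    finishing on a bound is named in ``boundary_flags``.
    """
    dens = _as_density(dist)
    d_c = dens.centers
    y = dens.values

    x0_model = options.init if options.init is not None else init_params(dist, options)
    x0 = _pack(x0_model)
    lb = np.array([options.fb_bounds[0], options.mu_bounds[0],
                   options.sigma_bounds[0], options.mu_bounds[0],
                   options.sigma_bounds[0]])
    ub = np.array([options.fb_bounds[1], options.mu_bounds[1],
                   options.sigma_bounds[1], options.mu_bounds[1],
                   options.sigma_bounds[1]])
    x0 = np.clip(x0, lb, ub)

    if options.objective == "poisson":
        # variance-stabilizing weights ~ 1/sqrt(max(y, eps))
        w = 1.0 / np.sqrt(np.maximum(y, 1e-3))
    elif options.objective == "lsq":
        w = np.ones_like(y)
    else:
        raise ValueError(f"unknown objective {options.objective!r}")

    def residuals(theta: np.ndarray) -> np.ndarray:
        return w * (y - model_density(_unpack(theta), d_c))

    res = optimize.least_squares(
        residuals, x0, bounds=(lb, ub), method="trf",
        xtol=options.tol, ftol=options.tol, gtol=options.tol,
        max_nfev=options.max_iter * len(x0),
    )
    model = _unpack(res.x).relabeled()
    plain = y - model_density(model, d_c)
    rss = float(plain @ plain)
    theta = _pack(model)
    atol = 1e-8
    flags = tuple(
        name for name, v, lo, hi in zip(_PARAM_NAMES, theta, lb, ub)
        if v - lo <= atol or hi - v <= atol
    )
    return FitResult(model=model, rss=rss, converged=bool(res.status > 0),
                     n_iter=int(res.nfev), boundary_flags=flags)


def fit_unimodal(dist: BinnedDistribution,
                 options: FitOptions = FitOptions()) -> FitResult:
    """Single log-normal fit, used as the null model for modality calls."""
    dens = _as_density(dist)
    d_c = dens.centers
    y = dens.values
    mass = y * dens.widths
    ln_d = np.log(d_c)
    mu0 = float(np.average(ln_d, weights=mass))
    sigma0 = math.sqrt(max(float(np.average((ln_d - mu0) ** 2, weights=mass)),
                           1e-6))
    lb = np.array([options.mu_bounds[0], options.sigma_bounds[0]])
    ub = np.array([options.mu_bounds[1], options.sigma_bounds[1]])
    x0 = np.clip([mu0, sigma0], lb, ub)

    def residuals(theta):
        return y - single_density(theta[0], theta[1], d_c)

    res = optimize.least_squares(residuals, x0, bounds=(lb, ub), method="trf",
                                 xtol=options.tol, ftol=options.tol,
                                 gtol=options.tol,
                                 max_nfev=options.max_iter * 2)
    mu, sigma = res.x
    r = y - single_density(mu, sigma, d_c)
    # degenerate mixture representation so downstream code sees one type
    model = MixtureModel(f_b=0.0, mu_a=float(mu), sigma_a=float(sigma),
                         mu_b=float(mu) - 1e-6, sigma_b=float(sigma))
    flags = tuple(name for name, v, lo, hi in
                  zip(("mu", "sigma"), res.x, lb, ub)
                  if v - lo <= 1e-8 or hi - v <= 1e-8)
    return FitResult(model=model, rss=float(r @ r),
                     converged=bool(res.status > 0), n_iter=int(res.nfev),
                     boundary_flags=flags)


def extract_phenotypes(fit: FitResult) -> dict:
    """Distribution phenotypes from a converged fit.

    ``mean_diam_*`` is the arithmetic mean exp(mu + sigma²/2) of the fitted
    volume-weighted component; the medians exp(mu) are reported alongside.
    """
    if not fit.converged:
        raise UnconvergedFitError(
            f"fit did not converge after {fit.n_iter} evaluations "
            f"(rss={fit.rss:.4g}); phenotypes withheld")
    m = fit.model
    return {
        "b_volume_percent": 100.0 * m.f_b,
        "mean_diam_A_um": m.mean_diam_a,
        "mean_diam_B_um": m.mean_diam_b,
        "median_diam_A_um": m.median_diam_a,
        "median_diam_B_um": m.median_diam_b,
    }


class Modality(str, enum.Enum):
    UNIMODAL = "unimodal"
    BIMODAL = "bimodal"
    INDETERMINATE = "indeterminate"


def classify_modality(dist: BinnedDistribution,
                      options: FitOptions = FitOptions(),
                      threshold: float = 10.0,
                      ) -> Tuple[Modality, float]:
    """AIC comparison of 1- vs 2-component fits.

    Returns (modality, evidence) where evidence = AIC₁ − AIC₂.  Bimodal
    requires evidence > ``threshold`` *and* an interior mixing fraction
    (f_b in [0.01, 0.99], off its bounds).
    """
    fit1 = fit_unimodal(dist, options)
    fit2 = fit_bimodal(dist, options)
    if not fit1.converged and not fit2.converged:
        return Modality.INDETERMINATE, float("nan")
    n = _as_density(dist).n_bins

    def aic(rss: float, k: int) -> float:
        return n * math.log(max(rss, 1e-300) / n) + 2 * k

    evidence = aic(fit1.rss, 2) - aic(fit2.rss, 5)
    interior = (0.01 <= fit2.model.f_b <= 0.99
                and "f_b" not in fit2.boundary_flags)
    if fit2.converged and evidence > threshold and interior:
        return Modality.BIMODAL, evidence
    return Modality.UNIMODAL, evidence
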