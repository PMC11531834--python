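import math

import numpy as np
import pytest

from granulefit.distributions import BinnedDistribution, make_log_edges
from granulefit.mixture import MixtureModel, model_density
from granulefit.simulate import default_panel_design, simulate_experiment


def density_to_percent_dist(model: MixtureModel, edges: np.ndarray,
                            meta=None) -> BinnedDistribution:
    """Noise-free volume-percent trace sampled from a mixture model."""
    d_c = np.sqrt(edges[:-1] * edges[1:])
    vals = model_density(model, d_c) * np.diff(edges)
    vals = 100.0 * vals / vals.sum()
    return BinnedDistribution(edges, vals, "volume", "percent",
                              meta=meta or {})


@pytest.fixture
def two_peak_model() -> MixtureModel:
    return MixtureModel(f_b=0.4, mu_a=math.log(22.0), sigma_a=0.25,
                        mu_b=math.log(5.0), sigma_b=0.3)


@pytest.fixture
def wide_edges() -> np.ndarray:
    # wide enough that the mixture's support is effectively fully covered
    return make_log_edges(0.8, 70.0, 256)


@pytest.fixture
def two_peak_dist(two_peak_model, wide_edges) -> BinnedDistribution:
    return density_to_percent_dist(two_peak_model, wide_edges)


@pytest.fixture(scope="session")
def small_panel(tmp_path_factory):
    """Tiny simulated genotype panel shared by pipeline/CLI tests."""
    out = tmp_path_factory.mktemp("panel")
    design = default_panel_design(n_plants=3, n_grains=2, n_granules=20_000)
    return simulate_experiment(design, out, base_seed=11)
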