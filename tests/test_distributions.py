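import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from granulefit.distributions import (BinnedDistribution, GranulePopulation,
                                      SamplePrep, ValueKind,
                                      average_distributions, bin_population,
                                      convert_weighting, counts_to_percent,
                                      from_density, make_log_edges,
                                      to_density)
from granulefit.errors import ContractError, EmptyDistributionError


class TestMakeLogEdges:
    def test_two_bins_forced_geometric(self):
        np.testing.assert_allclose(make_log_edges(1, 4, 2), [1, 2, 4])

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            make_log_edges(2, 2, 1)
        with pytest.raises(ValueError):
            make_log_edges(4, 1, 2)
        with pytest.raises(ValueError):
            make_log_edges(-1, 4, 2)
        with pytest.raises(ValueError):
            make_log_edges(1, 4, 0)

    def test_constant_ratio(self):
        edges = make_log_edges(1.4, 42, 400)
        assert edges.size == 401
        assert edges[0] == 1.4 and edges[-1] == 42
        ratios = edges[1:] / edges[:-1]
        np.testing.assert_allclose(ratios, (42 / 1.4) ** (1 / 400), rtol=1e-12)


class TestBinnedDistributionInvariants:
    def test_valid_percent(self):
        d = BinnedDistribution([1, 2, 4], [40, 60], "volume", "percent")
        assert d.n_bins == 2
        np.testing.assert_allclose(d.centers, [math.sqrt(2), math.sqrt(8)])

    @pytest.mark.parametrize("edges", [[2, 1, 4], [0, 1, 2], [1, 1, 2], [1]])
    def test_bad_edges(self, edges):
        with pytest.raises(ValueError):
            BinnedDistribution(edges, [50] * (len(edges) - 1), "volume",
                               "percent")

    def test_negative_and_nonfinite_values(self):
        with pytest.raises(ValueError):
            BinnedDistribution([1, 2, 4], [-1, 101], "volume", "percent")
        with pytest.raises(ValueError):
            BinnedDistribution([1, 2, 4], [np.nan, 100], "volume", "percent")

    def test_percent_must_sum_to_100(self):
        with pytest.raises(ValueError):
            BinnedDistribution([1, 2, 4], [40, 50], "volume", "percent")

    def test_density_must_integrate_to_100(self):
        BinnedDistribution([1, 2, 4], [40, 30], "volume", "percent_density")
        with pytest.raises(ValueError):
            BinnedDistribution([1, 2, 4], [40, 40], "volume", "percent_density")

    def test_immutable(self):
        d = BinnedDistribution([1, 2, 4], [40, 60], "volume", "percent")
        with pytest.raises(ValueError):
            d.values[0] = 1.0


class TestDensityTransforms:
    def test_example(self):
        d = BinnedDistribution([1, 2, 4], [40, 60], "volume", "percent")
        dens = to_density(d)
        np.testing.assert_allclose(dens.values, [40, 30])
        assert dens.value_kind is ValueKind.PERCENT_DENSITY

    def test_round_trip_identity(self):
        d = BinnedDistribution(make_log_edges(1.4, 42, 50),
                               np.full(50, 2.0), "volume", "percent")
        back = from_density(to_density(d))
        np.testing.assert_allclose(back.values, d.values, rtol=1e-12)

    def test_wrong_kind_rejected(self):
        d = BinnedDistribution([1, 2, 4], [1, 2], "number", "count")
        with pytest.raises(ContractError):
            to_density(d)
        with pytest.raises(ContractError):
            from_density(counts_to_percent(d))

    @given(values=st.lists(st.floats(0.01, 1e4), min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_integral_conserved(self, values):
        n = len(values)
        edges = make_log_edges(1.0, 50.0, n)
        pct = 100.0 * np.asarray(values) / np.sum(values)
        pct = pct * (100.0 / pct.sum())
        d = BinnedDistribution(edges, pct, "volume", "percent")
        dens = to_density(d)
        assert math.isclose(float((dens.values * dens.widths).sum()), 100.0,
                            rel_tol=1e-9)


class TestCountsToPercent:
    def test_examples(self):
        d = BinnedDistribution([1, 2, 3, 4], [1, 1, 2], "number", "count")
        np.testing.assert_allclose(counts_to_percent(d).values, [25, 25, 50])
        single = BinnedDistribution([1, 2], [5], "number", "count")
        np.testing.assert_allclose(counts_to_percent(single).values, [100])

    def test_all_zero_counts(self):
        d = BinnedDistribution([1, 2, 4], [0, 0], "number", "count")
        with pytest.raises(EmptyDistributionError):
            counts_to_percent(d)


class TestConvertWeighting:
    def test_d_cubed_ratio(self):
        # bins whose geometric-mean diameters are exactly 2 and 4 µm:
        # volume percents split by d³ ratio 1:8
        d = BinnedDistribution([1.6, 2.5, 6.4], [50, 50], "number", "percent")
        np.testing.assert_allclose(d.centers, [2, 4])
        vol = convert_weighting(d, "volume")
        np.testing.assert_allclose(vol.values, [100 / 9, 800 / 9])

    def test_single_bin_identity(self):
        d = BinnedDistribution([1, 4], [100.0], "number", "percent")
        np.testing.assert_allclose(convert_weighting(d, "volume").values, [100])

    def test_same_target_is_identity(self):
        d = BinnedDistribution([1, 4, 16], [50, 50], "number", "percent")
        assert convert_weighting(d, "number") is d

    def test_density_rejected(self):
        d = BinnedDistribution([1, 2, 4], [40, 30], "volume", "percent_density")
        with pytest.raises(ContractError):
            convert_weighting(d, "number")

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_involution(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        vals = rng.uniform(0.1, 10, n)
        vals = 100 * vals / vals.sum()
        d = BinnedDistribution(make_log_edges(1.4, 42, n), vals, "number",
                               "percent")
        back = convert_weighting(convert_weighting(d, "volume"), "number")
        np.testing.assert_allclose(back.values, d.values, rtol=1e-9)

    def test_against_direct_volume_binning(self):
        # Monte-Carlo oracle: convert number-binned percents vs binning
        # per-granule (π/6)d³ directly.
        rng = np.random.default_rng(7)
        diam = np.exp(rng.normal(math.log(12), 0.45, 100_000))
        diam = diam[(diam >= 1.4) & (diam <= 42)]
        pop = GranulePopulation(diam)
        edges = make_log_edges(1.4, 42, 40)
        number = bin_population(pop, edges, "number", value_kind="percent")
        converted = convert_weighting(number, "volume")
        direct = bin_population(pop, edges, "volume")
        sel = direct.values > 0.05  # avoid empty-bin relative error blowup
        np.testing.assert_allclose(converted.values[sel], direct.values[sel],
                                   rtol=0.02)


class TestBinPopulation:
    def test_number_counts(self):
        pop = GranulePopulation([1.5, 2.5, 2.6])
        d = bin_population(pop, [1, 2, 3], "number")
        np.testing.assert_allclose(d.values, [1, 2])
        assert d.value_kind is ValueKind.COUNT

    def test_volume_percent(self):
        pop = GranulePopulation([2.0, 4.0])
        d = bin_population(pop, [1, 3, 5], "volume")
        np.testing.assert_allclose(d.values, [100 / 9, 800 / 9])

    def test_overflow_reported_and_count_conserved(self):
        pop = GranulePopulation([0.5, 1.5, 2.5, 99.0])
        d = bin_population(pop, [1, 2, 3], "number")
        ov = d.meta["overflow"]
        assert ov["n_below"] == 1 and ov["n_above"] == 1
        assert d.values.sum() + ov["n_below"] + ov["n_above"] == len(pop)
        assert ov["volume_above"] == pytest.approx(math.pi / 6 * 99.0**3)

    def test_empty_population(self):
        with pytest.raises(EmptyDistributionError):
            bin_population(GranulePopulation([]), [1, 2], "number")
        with pytest.raises(EmptyDistributionError):
            bin_population(GranulePopulation([50.0]), [1, 2], "number")

    def test_half_open_bins_last_closed(self):
        d = bin_population(GranulePopulation([2.0, 3.0]), [1, 2, 3], "number")
        np.testing.assert_allclose(d.values, [0, 2])

    def test_lognormal_density_matches_analytic_pdf(self):
        # closed-form oracle at n = 10^6: expected per-bin mass from CDF
        # differences; 1% relative wherever expected counts make that
        # statistically meaningful (>= 10^4), 4σ binomial bound otherwise.
        n = 1_000_000
        rng = np.random.default_rng(123)
        diam = np.exp(rng.normal(math.log(20), 0.2, n))
        pop = GranulePopulation(diam)
        edges = make_log_edges(8, 50, 32)
        counts = bin_population(pop, edges, "number", value_kind="percent")
        dens = to_density(counts)
        ln = stats.lognorm(s=0.2, scale=20)
        p = np.diff(ln.cdf(edges))
        p_in = p / p.sum()  # renormalized to the window
        expected = 100 * p_in / dens.widths
        n_in = n - dens.meta["overflow"]["n_below"] - dens.meta["overflow"]["n_above"]
        sel = ln.pdf(dens.centers) > 0.001
        mc_sigma = expected * np.sqrt((1 - p_in) / (n_in * p_in))
        err = np.abs(dens.values - expected)
        assert np.all(err[sel] <= np.maximum(0.01 * expected[sel],
                                             4 * mc_sigma[sel]))
        # pure 1% relative where counting noise is negligible
        tight = sel & (n_in * p_in >= 3e4)
        assert tight.sum() >= 10
        np.testing.assert_allclose(dens.values[tight], expected[tight],
                                   rtol=0.01)


class TestAverageDistributions:
    def test_mean_of_percent(self):
        a = BinnedDistribution([1, 2, 4], [40, 60], "volume", "percent")
        b = BinnedDistribution([1, 2, 4], [60, 40], "volume", "percent")
        avg = average_distributions([a, b])
        np.testing.assert_allclose(avg.values, [50, 50])
        assert avg.meta["n_averaged"] == 2

    def test_mismatched_edges_rejected(self):
        a = BinnedDistribution([1, 2, 4], [40, 60], "volume", "percent")
        b = BinnedDistribution([1, 3, 4], [40, 60], "volume", "percent")
        with pytest.raises(ContractError):
            average_distributions([a, b])


class TestSamplePrep:
    def test_validation(self):
        with pytest.raises(ValueError):
            SamplePrep(2.0, 1.0, 100.0, 10)  # aliquot > total
        with pytest.raises(ValueError):
            SamplePrep(1.0, 100.0, 0.0, 10)
        with pytest.raises(ValueError):
            SamplePrep(1.0, 100.0, 100.0, -1)
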