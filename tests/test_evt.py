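import math

import numpy as np
import pytest
from scipy import integrate, stats

from spikevt import (
    DegenerateSampleError,
    MaximaSample,
    NormalizedHistogram,
    block_maxima,
    evt_pdf,
    fit_extreme,
    frechet_cdf,
    gumbel_cdf,
    ks_distance,
    make_stream,
    max_distribution_cdf,
    norming_constants,
    normalized_histogram,
    r_squared,
    weibull_cdf,
)


class TestLimitLawCdfs:
    def test_gumbel_anchor_and_limits(self):
        assert gumbel_cdf(0.0) == pytest.approx(math.exp(-1))
        assert gumbel_cdf(-50.0) == pytest.approx(0.0, abs=1e-12)
        assert gumbel_cdf(50.0) == pytest.approx(1.0)
        # median at loc - scale * ln(ln 2)
        med = 3.0 - 2.0 * math.log(math.log(2))
        assert gumbel_cdf(med, location=3.0, scale=2.0) == pytest.approx(0.5)

    def test_frechet_anchor_support_median(self):
        assert frechet_cdf(1.0, alpha=7.0) == pytest.approx(math.exp(-1))
        assert frechet_cdf(-0.5, alpha=2.0) == 0.0
        assert frechet_cdf(5.0, alpha=2.0, location=5.0, scale=1.0) == 0.0
        assert frechet_cdf(math.log(2) ** -0.5, alpha=2.0) == pytest.approx(0.5)

    def test_weibull_anchor_and_exponential_reduction(self):
        assert weibull_cdf(0.0, alpha=3.0) == pytest.approx(1.0)
        assert weibull_cdf(-1.0, alpha=1.0) == pytest.approx(math.exp(-1))
        x = np.linspace(-5, 0, 50)
        np.testing.assert_allclose(weibull_cdf(x, alpha=1.0), np.exp(x))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gumbel_cdf(0.0, scale=-1.0)
        with pytest.raises(ValueError):
            frechet_cdf(1.0, alpha=0.0)

    @pytest.mark.parametrize(
        "family, alpha",
        [("gumbel", None), ("frechet", 2.0), ("frechet", 20.0),
         ("weibull", 1.5), ("weibull", 4.0)],
    )
    def test_nondecreasing_with_unit_range(self, family, alpha):
        from spikevt import evt_cdf

        x = np.linspace(-30, 30, 1000)
        vals = evt_cdf(family, x, alpha, location=1.0, scale=2.5)
        assert np.all(np.diff(vals) >= 0)
        assert vals[0] < 1e-3
        assert vals[-1] > 0.95
        assert np.all((vals >= 0) & (vals <= 1))

    def test_agreement_with_scipy_reference(self):
        x = np.linspace(-10, 30, 500)
        np.testing.assert_allclose(
            gumbel_cdf(x, 3.0, 2.0), stats.gumbel_r.cdf(x, loc=3.0, scale=2.0)
        )
        np.testing.assert_allclose(
            frechet_cdf(x, 4.0, 1.0, 2.0),
            stats.invweibull.cdf(x, 4.0, loc=1.0, scale=2.0),
        )
        np.testing.assert_allclose(
            weibull_cdf(x, 3.0, 5.0, 2.0),
            stats.weibull_max.cdf(x, 3.0, loc=5.0, scale=2.0),
        )


class TestEvtPdf:
    def test_gumbel_standard_mode_anchor(self):
        assert evt_pdf("gumbel", 0.0) == pytest.approx(math.exp(-1))

    @pytest.mark.parametrize(
        "family, alpha, lo, hi",
        [("gumbel", None, -30.0, 60.0), ("frechet", 3.0, 1.0, np.inf),
         ("weibull", 2.5, -np.inf, 1.0)],
    )
    def test_integrates_to_one(self, family, alpha, lo, hi):
        val, _ = integrate.quad(
            lambda x: evt_pdf(family, x, alpha, location=1.0, scale=2.0), lo, hi
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize(
        "family, alpha", [("gumbel", None), ("frechet", 5.0), ("weibull", 2.5)]
    )
    def test_matches_cdf_central_difference(self, family, alpha):
        from spikevt import evt_cdf

        h = 1e-6
        if family == "gumbel":
            probes = np.linspace(-4, 8, 100)
        elif family == "frechet":
            probes = np.linspace(1.1, 9, 100)
        else:
            probes = np.linspace(-8, 0.9, 100)
        num = (evt_cdf(family, probes + h, alpha, 1.0, 2.0)
               - evt_cdf(family, probes - h, alpha, 1.0, 2.0)) / (2 * h)
        np.testing.assert_allclose(
            evt_pdf(family, probes, alpha, 1.0, 2.0), num, atol=1e-6
        )


class TestMaxDistributionCdf:
    def test_single_sample_identity(self):
        f = lambda x: stats.expon.cdf(x)
        x = np.linspace(0, 5, 50)
        np.testing.assert_allclose(max_distribution_cdf(f, 1, x), f(x))

    def test_exponential_block_of_100(self):
        # F(log 100)^100 = 0.99^100
        val = max_distribution_cdf(stats.expon.cdf, 100, math.log(100))
        assert val == pytest.approx(0.99 ** 100)
        assert val == pytest.approx(0.366032, abs=1e-6)

    def test_rejects_empty_block(self):
        with pytest.raises(ValueError):
            max_distribution_cdf(stats.expon.cdf, 0, 1.0)

    def test_monte_carlo_maxima_agree(self):
        # brute-force oracle: empirical CDF of the max of 50 uniforms
        m, n = 20_000, 50
        rng = np.random.default_rng(0)
        maxima = rng.random((m, n)).max(axis=1)
        d = ks_distance(maxima, lambda x: max_distribution_cdf(
            lambda y: np.clip(y, 0, 1), n, x))
        assert d < 3 / math.sqrt(m)


class TestNormingConstants:
    def test_exponential_population(self):
        nc = norming_constants("exponential", 1000)
        assert nc.a_n == 1.0
        assert nc.b_n == pytest.approx(math.log(1000))
        assert norming_constants("exponential", 1).b_n == 0.0

    def test_pareto_population(self):
        nc = norming_constants("pareto", 1000, alpha=20.0)
        assert nc.a_n == pytest.approx(1000 ** 0.05)
        assert nc.b_n == 0.0

    def test_pareto_requires_alpha(self):
        with pytest.raises(ValueError):
            norming_constants("pareto", 1000)


class TestBlockMaxima:
    def test_per_block_maximum(self):
        sample = block_maxima([[3, 9, 4], [7, 7], [1, 2, 10]])
        np.testing.assert_array_equal(sample.values, [9, 7, 10])
        assert sample.m == 3
        assert sample.mean_block_size == pytest.approx(8 / 3)

    def test_empty_blocks_skipped(self):
        sample = block_maxima([[5.0], [], [2.0, 3.0]])
        np.testing.assert_array_equal(sample.values, [5.0, 3.0])
        with pytest.raises(ValueError):
            block_maxima([[], []])

    def test_maxima_follow_power_of_population_cdf(self):
        # maxima of blocks of 30 standard exponentials vs F^30
        m, n = 10_000, 30
        rng = np.random.default_rng(1)
        blocks = rng.exponential(size=(m, n))
        sample = block_maxima(list(blocks))
        d = ks_distance(sample.values,
                        lambda x: max_distribution_cdf(stats.expon.cdf, n, x))
        assert d < 0.02


class TestNormalizedHistogram:
    def test_counting(self):
        hist = normalized_histogram([1.0, 1.0, 2.0], 1.0)
        np.testing.assert_allclose(hist.masses, [2 / 3, 1 / 3])
        np.testing.assert_allclose(hist.bin_edges, [1.0, 2.0, 3.0])

    def test_masses_sum_to_one(self):
        vals = np.random.default_rng(2).gamma(5, size=1000) + 1
        hist = normalized_histogram(vals, 0.25)
        assert hist.masses.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_and_bad_width_rejected(self):
        with pytest.raises(ValueError):
            normalized_histogram([], 1.0)
        with pytest.raises(ValueError):
            normalized_histogram([1.0], 0.0)

    def test_bin_masses_match_analytic_probabilities(self):
        # standard Gumbel draws at 0.1 ms bins vs CDF differences
        n = 100_000
        draws = stats.gumbel_r.rvs(size=n, random_state=np.random.default_rng(3))
        hist = normalized_histogram(draws, 0.1)
        probs = np.diff(gumbel_cdf(hist.bin_edges))
        se = np.sqrt(probs * (1 - probs) / n)
        # +3/n Poisson slack: near-empty tail bins hold 0-3 counts while
        # their binomial standard error is essentially zero
        assert np.all(np.abs(hist.masses - probs) <= 4 * se + 3.0 / n)


class TestGoodnessOfFit:
    def test_r_squared_anchors(self):
        obs = [0.2, 0.5, 0.3]
        assert r_squared(obs, obs) == pytest.approx(1.0)
        assert r_squared(obs, [np.mean(obs)] * 3) == pytest.approx(0.0)
        assert r_squared(obs, [0.25, 0.45, 0.3]) == pytest.approx(1 - 0.005 / (0.14 / 3))

    def test_r_squared_validation(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 1.0])  # zero variance
        with pytest.raises(ValueError):
            r_squared([1.0, 2.0], [1.0, 2.0])  # too few points

    def test_ks_distance_anchors(self):
        # location ln(ln 2) puts the Gumbel median at zero
        assert ks_distance([0.0], lambda x: gumbel_cdf(x, math.log(math.log(2)), 1.0)) == \
            pytest.approx(0.5, abs=1e-9)
        assert ks_distance([-100.0, -90.0], lambda x: gumbel_cdf(np.asarray(x))) == \
            pytest.approx(1.0, abs=1e-9)

    def test_ks_distance_calibration(self):
        # for a correctly specified CDF the statistic is ~ 1.95/sqrt(n)
        # at the 95% point; check across 10 independent seeds
        n = 100_000
        hits = 0
        for seed in range(10):
            draws = stats.gumbel_r.rvs(size=n, random_state=np.random.default_rng(seed))
            if ks_distance(draws, gumbel_cdf) < 1.95 / math.sqrt(n):
                hits += 1
        assert hits >= 8


class TestFitExtreme:
    def test_gumbel_mle_parameter_recovery(self):
        draws = stats.gumbel_r.rvs(loc=40, scale=5, size=20_000,
                                   random_state=np.random.default_rng(4))
        fit = fit_extreme(MaximaSample(draws, draws.size), "gumbel", "mle")
        assert fit.location == pytest.approx(40.0, abs=0.15)
        assert fit.scale == pytest.approx(5.0, abs=0.15)
        assert fit.r_squared > 0.98

    def test_frechet_mle_shape_recovery(self):
        draws = stats.invweibull.rvs(20, loc=0, scale=28, size=100_000,
                                     random_state=np.random.default_rng(5))
        fit = fit_extreme(MaximaSample(draws, draws.size), "frechet", "mle")
        assert fit.shape_alpha == pytest.approx(20.0, rel=0.1)

    def test_histogram_fit_of_its_own_generator_is_perfect(self):
        # histogram constructed exactly from a Gumbel pdf on bin centers
        edges = np.arange(10.0, 80.0, 1.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        masses = evt_pdf("gumbel", centers, None, 40.0, 5.0) * 1.0
        masses = masses / masses.sum()
        hist = NormalizedHistogram(edges, masses)
        fit = fit_extreme(hist, "gumbel", "histogram_ls")
        assert fit.r_squared == pytest.approx(1.0, abs=1e-6)
        assert fit.location == pytest.approx(40.0, abs=0.05)
        assert fit.scale == pytest.approx(5.0, abs=0.05)

    def test_histogram_ls_gumbel_recovery_from_draws(self):
        draws = stats.gumbel_r.rvs(loc=40, scale=5, size=50_000,
                                   random_state=np.random.default_rng(6))
        fit = fit_extreme(MaximaSample(draws, draws.size), "gumbel",
                          "histogram_ls", bin_width=1.0)
        assert fit.location == pytest.approx(40.0, abs=0.2)
        assert fit.scale == pytest.approx(5.0, abs=0.2)
        assert fit.r_squared > 0.99

    def test_fit_invariant_to_bin_origin_shift(self):
        draws = stats.gumbel_r.rvs(loc=40, scale=5, size=50_000,
                                   random_state=np.random.default_rng(7))
        fit_a = fit_extreme(MaximaSample(draws, draws.size), "gumbel",
                            "histogram_ls")
        shifted = draws + 0.4  # moves every bin edge by a sub-bin offset
        fit_b = fit_extreme(MaximaSample(shifted, shifted.size), "gumbel",
                            "histogram_ls")
        assert fit_b.location - fit_a.location == pytest.approx(0.4, abs=0.1)
        assert fit_b.scale == pytest.approx(fit_a.scale, rel=0.03)

    def test_degenerate_sample_refused(self):
        flat = MaximaSample(np.full(500, 36.0), 500)
        with pytest.raises(DegenerateSampleError):
            fit_extreme(flat, "gumbel", "mle")
        with pytest.raises(DegenerateSampleError):
            fit_extreme(flat, "gumbel", "histogram_ls")

    def test_mle_requires_raw_maxima(self):
        hist = normalized_histogram([1.0, 2.0, 3.0, 2.5], 1.0)
        with pytest.raises(ValueError):
            fit_extreme(hist, "gumbel", "mle")
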