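"""Moment/shape/entropy summaries vs Monte-Carlo and closed-form oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from lkmefit.distribution import LkmeParams, log_pdf, pdf, cdf, sample
from lkmefit.properties import (
    galton_skewness,
    mean,
    mgf,
    moors_kurtosis,
    order_stat_pdf,
    properties_report,
    pwm,
    raw_moment,
    renyi_entropy,
    shannon_entropy,
    variance,
)

UNIT = LkmeParams(1.0, 1.0, 1.0, 0.0)
SKEWED = LkmeParams(1.8, 1.2, 1.5, 0.3)

# closed form: E[X] = Ein(1)/(e-1) = sum 1/(n n!) / (e-1) at the unit point
UNIT_MEAN = 0.7669883540794344


def _mc(params, n=1_000_000, seed=5):
    return sample(params, n, seed=seed).values


class TestMoments:
    def test_zeroth_moment_is_one(self):
        assert raw_moment(SKEWED, 0) == 1.0

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            raw_moment(UNIT, -1)

    def test_unit_mean_closed_form(self):
        assert raw_moment(UNIT, 1) == pytest.approx(UNIT_MEAN, abs=1e-9)

    def test_unit_variance_quadrature_oracle(self):
        assert variance(UNIT) == pytest.approx(0.7462003740244335, abs=1e-8)

    def test_moments_match_monte_carlo(self):
        s = _mc(SKEWED)
        se1 = s.std() / math.sqrt(s.size)
        assert abs(mean(SKEWED) - s.mean()) < 3 * se1
        se2 = (s**2).std() / math.sqrt(s.size)
        assert abs(raw_moment(SKEWED, 2) - (s**2).mean()) < 3 * se2

    def test_variance_nonnegative_and_scales(self, random_param_vectors):
        for p in random_param_vectors[:20]:
            assert variance(p) >= 0.0
        c = 2.5
        scaled = LkmeParams(SKEWED.alpha, SKEWED.beta, c * SKEWED.theta, c * SKEWED.lam)
        assert variance(scaled) == pytest.approx(c**2 * variance(SKEWED), rel=1e-6)

    @pytest.mark.parametrize("a", [1, 2, 3])
    def test_integer_alpha_series_cross_check(self, a):
        """Linear-representation series of the raw moment (exponential
        expansion of the outer exp of the density, term-wise Gamma-kernel
        integral, truncated at i <= 60) must agree with quadrature —
        the only sanctioned use of the series route."""
        from math import comb, factorial, gamma

        def series_moment(params, r, imax=60):
            al, b, th, lam = params
            total = 0.0
            for i in range(imax):
                for k in range(r + 1):
                    total += (
                        comb(r, k) * th**k * (-lam) ** (r - k)
                        * gamma(k / al + 1.0)
                        / (factorial(i) * (b * (i + 1)) ** (k / al))
                        / (i + 1)
                    )
            return total / (math.e - 1)

        p = LkmeParams(float(a), 1.3, 1.1, 0.4)
        for r in (1, 2):
            assert series_moment(p, r) == pytest.approx(raw_moment(p, r), rel=1e-4)


class TestShape:
    def test_galton_zero_for_symmetric_quantiles(self):
        # a symmetric quantile triple gives zero numerator in both variants
        # (checked through the affine-invariance of the statistic instead
        # of a contrived symmetric distribution)
        g1 = galton_skewness(SKEWED, "conventional")
        shifted = LkmeParams(SKEWED.alpha, SKEWED.beta, SKEWED.theta, SKEWED.lam + 5.0)
        assert galton_skewness(shifted, "conventional") == pytest.approx(g1, rel=1e-9)
        scaled = LkmeParams(SKEWED.alpha, SKEWED.beta, 3.0 * SKEWED.theta, 3.0 * SKEWED.lam)
        assert galton_skewness(scaled, "conventional") == pytest.approx(g1, rel=1e-9)

    def test_galton_matches_monte_carlo_quartiles(self):
        s = _mc(UNIT, seed=9)
        q1, q2, q3 = np.percentile(s, [25, 50, 75])
        brute = (q3 - 2 * q2 + q1) / (q3 - q1)
        assert galton_skewness(UNIT, "conventional") == pytest.approx(brute, abs=5e-3)

    def test_moors_conventional_on_normal_octiles(self):
        q = stats.norm.ppf
        val = (q(7 / 8) - q(5 / 8) + q(3 / 8) - q(1 / 8)) / (q(6 / 8) - q(2 / 8))
        assert val == pytest.approx(1.233, abs=1e-3)

    def test_variants_differ_on_asymmetric_law(self):
        assert galton_skewness(SKEWED, "as-printed") != pytest.approx(
            galton_skewness(SKEWED, "conventional"), abs=1e-6)
        assert moors_kurtosis(SKEWED, "as-printed") != pytest.approx(
            moors_kurtosis(SKEWED, "conventional"), abs=1e-6)

    def test_moors_scale_shift_invariant(self):
        m = moors_kurtosis(SKEWED)
        moved = LkmeParams(SKEWED.alpha, SKEWED.beta, 4.0 * SKEWED.theta,
                           4.0 * SKEWED.lam + 2.0)
        # theta scaling with lam moved arbitrarily: kurtosis is quantile-ratio based
        assert moors_kurtosis(moved) == pytest.approx(m, rel=1e-9)


class TestMgfPwm:
    def test_mgf_at_zero(self):
        assert mgf(SKEWED, 0.0) == 1.0

    def test_mgf_derivative_is_mean(self):
        h = 1e-4
        d = (mgf(SKEWED, h) - mgf(SKEWED, -h)) / (2 * h)
        assert d == pytest.approx(mean(SKEWED), rel=1e-5)

    def test_mgf_divergence_guards(self):
        with pytest.raises(ValueError):
            mgf(LkmeParams(0.5, 1.0, 1.0, 0.0), 0.5)
        with pytest.raises(ValueError):
            mgf(UNIT, 1.0)  # alpha=1 needs t < beta/theta
        assert 0.0 < mgf(UNIT, -1.0) <= 1.0

    def test_pwm_reductions(self):
        assert pwm(SKEWED, 2, 0) == pytest.approx(raw_moment(SKEWED, 2), rel=1e-9)
        for s_ord in (1, 2, 5):
            assert pwm(SKEWED, 0, s_ord) == pytest.approx(1.0 / (s_ord + 1), rel=1e-12)

    def test_pwm_matches_monte_carlo(self):
        s = _mc(SKEWED, seed=13)
        xf = s * np.asarray(cdf(s, SKEWED))
        se = xf.std() / math.sqrt(xf.size)
        assert abs(pwm(SKEWED, 1, 1) - xf.mean()) < 3 * se


class TestOrderStats:
    def test_rank_validation(self):
        with pytest.raises(ValueError):
            order_stat_pdf(UNIT, 0, 5, 1.0)
        with pytest.raises(ValueError):
            order_stat_pdf(UNIT, 6, 5, 1.0)

    def test_n1_reduces_to_pdf(self):
        x = np.linspace(0.05, 4.0, 25)
        np.testing.assert_allclose(
            order_stat_pdf(UNIT, 1, 1, x), pdf(x, UNIT), rtol=1e-12)

    def test_normalizes(self):
        from scipy import integrate

        total, _ = integrate.quad(
            lambda x: float(order_stat_pdf(SKEWED, 2, 5, x)),
            -SKEWED.lam, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_minimum_density_matches_sampling(self):
        """Histogram of minima of 1e5 five-draw samples vs the r=1,n=5 law."""
        rng = np.random.default_rng(23)
        u = rng.uniform(size=(100_000, 5))
        from lkmefit.distribution import quantile

        minima = np.min(np.asarray(quantile(u, UNIT)), axis=1)
        edges = np.quantile(minima, np.linspace(0, 1, 21))
        edges[0], edges[-1] = 0.0, np.inf
        counts, _ = np.histogram(minima, edges)
        # expected cell probabilities from the order-statistic CDF:
        # P(min <= x) = 1 - (1 - F(x))^5
        Fmin = lambda x: 1 - (1 - np.asarray(cdf(x, UNIT))) ** 5
        probs = np.diff([0] + [Fmin(e) for e in edges[1:-1]] + [1])
        chi2 = np.sum((counts - 1e5 * probs) ** 2 / (1e5 * probs))
        assert stats.chi2.sf(chi2, len(counts) - 1) > 0.01


class TestEntropy:
    def test_shannon_matches_monte_carlo(self):
        s = _mc(SKEWED, seed=17)
        lp = np.asarray(log_pdf(s, SKEWED))
        se = lp.std() / math.sqrt(lp.size)
        assert abs(shannon_entropy(SKEWED) + lp.mean()) < 3 * se

    def test_renyi_u2_matches_expectation_of_density(self):
        s = _mc(SKEWED, seed=19)
        fs = np.asarray(pdf(s, SKEWED))
        se = fs.std() / math.sqrt(fs.size)
        mc = -math.log(fs.mean())
        quad = renyi_entropy(SKEWED, 2.0)
        assert abs(math.exp(-quad) - fs.mean()) < 3 * se
        assert quad == pytest.approx(mc, abs=3 * se / fs.mean())

    def test_renyi_continuity_at_one(self):
        sh = shannon_entropy(SKEWED)
        assert renyi_entropy(SKEWED, 0.999) == pytest.approx(sh, abs=2e-3)
        assert renyi_entropy(SKEWED, 1.001) == pytest.approx(sh, abs=2e-3)

    def test_entropy_scaling_law(self):
        c = 3.0
        scaled = LkmeParams(SKEWED.alpha, SKEWED.beta, c * SKEWED.theta, c * SKEWED.lam)
        assert shannon_entropy(scaled) == pytest.approx(
            shannon_entropy(SKEWED) + math.log(c), rel=1e-6)
        assert renyi_entropy(scaled, 2.0) == pytest.approx(
            renyi_entropy(SKEWED, 2.0) + math.log(c), rel=1e-6)
        # pure location change leaves entropy untouched
        shifted = LkmeParams(SKEWED.alpha, SKEWED.beta, SKEWED.theta, SKEWED.lam - 0.2)
        assert shannon_entropy(shifted) == pytest.approx(shannon_entropy(SKEWED), rel=1e-8)

    def test_renyi_domain_errors(self):
        with pytest.raises(ValueError):
            renyi_entropy(SKEWED, 1.0)
        with pytest.raises(ValueError):
            renyi_entropy(SKEWED, -0.5)
        with pytest.raises(ValueError):
            renyi_entropy(LkmeParams(0.4, 1, 1, 0), 3.0)  # f^u not integrable


def test_properties_report_keys():
    rep = properties_report(SKEWED)
    assert rep["mean"] == pytest.approx(mean(SKEWED), rel=1e-9)
    assert rep["compound_beta_over_theta_alpha"] == pytest.approx(
        SKEWED.beta / SKEWED.theta**SKEWED.alpha)
    assert set(rep) >= {"median", "variance", "galton_skewness",
                        "moors_kurtosis", "shannon_entropy"}
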