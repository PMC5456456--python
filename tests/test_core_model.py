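"""Closed-form model mathematics against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from gwasmix.core_model import (
    DesignContext,
    MixtureParams,
    decompose,
    local_fdr,
    marginal_density,
    marginal_log_density,
    posterior_mean,
    posterior_second_moment,
    posterior_variance,
    replication_probability,
    tweedie_posterior,
)

from conftest import random_triples


def posterior_moments_by_quadrature(z, theta, design):
    """Independent oracle: integrate the posterior of sqrt(n)*delta directly.

    The prior of d = sqrt(n)*delta is the scale mixture with component
    variances s_j = X sigma_j^2(tot); the posterior is proportional to
    prior(d) * phi((z - d)/sigma0).  Returns (mean, variance, second moment,
    large-component second-moment contribution).
    """
    comp = decompose(theta, design)
    s0 = math.sqrt(theta.sigma0_sq)
    sds = np.sqrt(comp.s)
    weights = [theta.pi1, theta.pi2]

    def component_integral(j, power):
        if sds[j] == 0.0:
            val = 0.0 if power else stats.norm.pdf(z, scale=s0)
            return weights[j] * val
        f = lambda d: weights[j] * stats.norm.pdf(d, scale=sds[j]) * \
            stats.norm.pdf(z - d, scale=s0) * d**power
        lo, hi = -14 * sds[j], 14 * sds[j]
        return integrate.quad(f, lo, hi, limit=500, epsabs=1e-14, epsrel=1e-12)[0]

    norm = sum(component_integral(j, 0) for j in (0, 1))
    m1 = sum(component_integral(j, 1) for j in (0, 1)) / norm
    m2 = sum(component_integral(j, 2) for j in (0, 1)) / norm
    m2_large = component_integral(1, 2) / norm
    return m1, m2 - m1**2, m2, m2_large


class TestMarginalDensity:
    def test_reduces_to_standard_normal(self):
        theta = MixtureParams(pi1=1.0, sigma0_sq=1.0, sigma1_sq=0.0, sigma2_sq=0.5)
        d = DesignContext(n_eff=1234.0, p_bar=0.3)
        assert marginal_density(0.0, theta, d) == pytest.approx(0.3989422804014327, rel=1e-10)

    def test_two_term_evaluation(self):
        # independent evaluation through scipy's normal pdf
        theta = MixtureParams(pi1=0.99, sigma0_sq=1.0, sigma1_sq=0.0, sigma2_sq=0.01)
        d = DesignContext.from_het_scale(1000.0)
        expected = 0.99 * stats.norm.pdf(3.0) + 0.01 * stats.norm.pdf(3.0, scale=math.sqrt(11.0))
        assert marginal_density(3.0, theta, d) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("pi1", [0.9, 0.999])
    def test_normalizes(self, pi1):
        theta = MixtureParams(pi1=pi1, sigma0_sq=1.1, sigma1_sq=1e-5, sigma2_sq=5e-3)
        d = DesignContext(n_eff=5000.0, p_bar=0.25)
        total, _ = integrate.quad(lambda z: marginal_density(z, theta, d), -np.inf, np.inf)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_symmetric_positive_and_rejects_nonfinite(self):
        theta = MixtureParams(pi1=0.95, sigma0_sq=1.0, sigma1_sq=1e-6, sigma2_sq=1e-3)
        d = DesignContext(n_eff=8000.0, p_bar=0.3)
        z = np.linspace(0, 30, 7)
        assert np.all(marginal_density(z, theta, d) > 0)
        np.testing.assert_allclose(marginal_density(z, theta, d),
                                   marginal_density(-z, theta, d), rtol=1e-12)
        with pytest.raises(ValueError):
            marginal_density(np.nan, theta, d)


class TestLocalFdr:
    def test_degenerate_cases(self, design):
        all_small = MixtureParams(pi1=1.0, sigma0_sq=1.0, sigma1_sq=0.0, sigma2_sq=0.3)
        assert local_fdr(np.array([0.0, 3.0, 9.0]), all_small, design) == pytest.approx(1.0)
        same_components = MixtureParams(pi1=0.7, sigma0_sq=1.0, sigma1_sq=1e-5, sigma2_sq=0.0)
        assert local_fdr(np.array([0.0, 4.0]), same_components, design) == pytest.approx(0.7)

    def test_bayes_rule_and_monotone_decrease(self):
        theta = MixtureParams(pi1=0.99, sigma0_sq=1.0, sigma1_sq=0.0, sigma2_sq=0.01)
        d = DesignContext.from_het_scale(1000.0)
        z = np.array([0.0, 2.0, 5.0])
        f1 = 0.99 * stats.norm.pdf(z, scale=1.0)
        f2 = 0.01 * stats.norm.pdf(z, scale=math.sqrt(11.0))
        np.testing.assert_allclose(local_fdr(z, theta, d), f1 / (f1 + f2), rtol=1e-12)
        fdr = local_fdr(z, theta, d)
        assert fdr[0] > fdr[1] > fdr[2]

    def test_survives_extreme_tails(self, cd_like_theta, design):
        fdr = local_fdr(np.array([-50.0, 50.0]), cd_like_theta, design)
        assert np.all(np.isfinite(fdr)) and np.all(fdr >= 0.0)

    @given(z=st.floats(-20, 20))
    def test_fdr_tdr_partition(self, z, cd_like_theta, design):
        fdr = float(local_fdr(z, cd_like_theta, design))
        assert 0.0 <= fdr <= 1.0


class TestPosteriorMoments:
    def test_point_mass_prior_gives_zero(self, design):
        theta = MixtureParams(pi1=0.9, sigma0_sq=1.0, sigma1_sq=0.0, sigma2_sq=0.0)
        z = np.array([-3.0, 0.0, 4.0])
        assert posterior_mean(z, theta, design) == pytest.approx(0.0)
        assert posterior_variance(z, theta, design) == pytest.approx(0.0, abs=1e-12)
        assert posterior_second_moment(z, theta, design, "all") == pytest.approx(0.0, abs=1e-12)
        assert posterior_second_moment(z, theta, design, "large_only") == pytest.approx(0.0, abs=1e-12)

    @given(z=st.floats(-10, 10), pi1=st.floats(0.5, 0.999))
    def test_odd_symmetry_and_shrinkage(self, z, pi1, design):
        theta = MixtureParams(pi1=pi1, sigma0_sq=1.0, sigma1_sq=1e-6, sigma2_sq=2e-3)
        mu = float(posterior_mean(z, theta, design))
        assert mu == pytest.approx(-float(posterior_mean(-z, theta, design)), abs=1e-12)
        assert abs(mu) <= abs(z) + 1e-12

    def test_matches_tweedie_identity(self):
        # Eq-13/14-style closed forms vs the Tweedie formulas applied to the
        # marginal by numerical differentiation, on a randomized grid
        for theta, d, z in random_triples(60, seed=1):
            mu = float(posterior_mean(z, theta, d))
            var = float(posterior_variance(z, theta, d))
            tm, tv = tweedie_posterior(
                z, lambda x: marginal_log_density(x, theta, d), theta.sigma0_sq)
            assert mu == pytest.approx(float(tm), rel=1e-6, abs=1e-8)
            assert var == pytest.approx(float(tv), rel=1e-6, abs=1e-8)

    def test_matches_quadrature_oracle(self):
        for theta, d, z in random_triples(12, seed=2):
            m1, var, m2, m2_large = posterior_moments_by_quadrature(z, theta, d)
            assert float(posterior_mean(z, theta, d)) == pytest.approx(m1, rel=1e-6, abs=1e-9)
            assert float(posterior_variance(z, theta, d)) == pytest.approx(var, rel=1e-6, abs=1e-9)
            assert float(posterior_second_moment(z, theta, d, "all")) == \
                pytest.approx(m2, rel=1e-6, abs=1e-9)
            assert float(posterior_second_moment(z, theta, d, "large_only")) == \
                pytest.approx(m2_large, rel=1e-6, abs=1e-9)

    def test_large_component_bounded_by_total(self, cd_like_theta, design):
        z = np.linspace(-8, 8, 33)
        all_ = posterior_second_moment(z, cd_like_theta, design, "all")
        large = posterior_second_moment(z, cd_like_theta, design, "large_only")
        assert np.all(large <= all_ + 1e-12)

    def test_fdr_log_derivative_relation(self, cd_like_theta, design):
        # -d/dz log fdr equals the gap between the overall and the
        # small-component posterior means, divided by sigma0^2
        comp = decompose(cd_like_theta, design)
        h = 1e-5
        for z in (0.5, 2.0, 4.0):
            lhs = -(math.log(local_fdr(z + h, cd_like_theta, design))
                    - math.log(local_fdr(z - h, cd_like_theta, design))) / (2 * h)
            mu = float(posterior_mean(z, cd_like_theta, design))
            mu_small = z * comp.signal_var_small / comp.marginal_var_small
            assert lhs == pytest.approx((mu - mu_small) / cd_like_theta.sigma0_sq,
                                        rel=1e-4, abs=1e-7)


class TestReplicationProbability:
    def test_pure_null_independence(self):
        theta = MixtureParams(pi1=0.9, sigma0_sq=1.0, sigma1_sq=0.0, sigma2_sq=0.0)
        d = DesignContext(n_eff=5000.0, p_bar=0.3)
        p = replication_probability(np.array([0.0, 2.0, 7.0]), theta, d, d, 1.645)
        assert p == pytest.approx(stats.norm.cdf(-1.645), abs=1e-4)

    def test_infinite_replication_limit(self, design):
        """With sigma1 = 0 and n_r -> infinity the rate tends to tdr(z).

        The exact limit is tdr(z) + fdr(z) * Phi(-c_alpha) — a null SNP still
        crosses the fixed threshold by chance — so the tdr approximation is
        checked where the components are well separated (fdr ~ 0) and the
        exact limit identity is checked everywhere.
        """
        theta = MixtureParams(pi1=0.99, sigma0_sq=1.0, sigma1_sq=0.0, sigma2_sq=2e-3)
        c_alpha = 1.645
        d_rep = DesignContext(n_eff=design.n_eff * 1e9, p_bar=design.p_bar)
        z = np.array([1.0, 2.5, 4.0, 5.5, 7.0])
        fdr = local_fdr(z, theta, design)
        p = replication_probability(z, theta, design, d_rep, c_alpha)
        # independent derivation of the limit: as n_r grows the large-effect
        # branch tends to the posterior sign-agreement probability and the
        # sharp-null branch to the chance crossing rate
        comp = decompose(theta, design)
        sign_agree = stats.norm.cdf(
            np.abs(z) * math.sqrt(comp.signal_var_large / comp.marginal_var_large)
            / math.sqrt(theta.sigma0_sq))
        exact_limit = (1.0 - fdr) * sign_agree + fdr * stats.norm.cdf(-c_alpha)
        np.testing.assert_allclose(p, exact_limit, atol=1e-6)
        separated = fdr < 1e-2
        assert separated.any()
        np.testing.assert_allclose(p[separated], (1.0 - fdr)[separated], atol=1e-3)

    def test_monotone_in_replication_size_and_z(self, cd_like_theta, design):
        z = np.linspace(0.0, 8.0, 17)
        prev = None
        for mult in (0.25, 0.5, 1.0, 2.0, 4.0):
            d_rep = DesignContext(n_eff=design.n_eff * mult, p_bar=design.p_bar)
            p = replication_probability(z, cd_like_theta, design, d_rep, 1.645)
            assert np.all(np.diff(p) >= -1e-12)  # non-decreasing in |z|
            if prev is not None:
                assert np.all(p >= prev - 1e-12)  # non-decreasing in n_r
            prev = p

    def test_rejects_bad_threshold(self, cd_like_theta, design):
        with pytest.raises(ValueError):
            replication_probability(1.0, cd_like_theta, design, design, 0.0)


class TestTweedieOracle:
    def test_pure_null_marginal(self):
        s0sq = 1.3
        logf = lambda z: stats.norm.logpdf(z, scale=math.sqrt(s0sq))
        mean, var = tweedie_posterior(np.array([0.0, 1.7, -3.0]), logf, s0sq)
        assert mean == pytest.approx(0.0, abs=1e-6)
        assert var == pytest.approx(0.0, abs=1e-4)

    def test_conjugate_normal_closed_form(self):
        s0sq, s = 1.0, 4.0
        logf = lambda z: stats.norm.logpdf(z, scale=math.sqrt(s0sq + s))
        z = np.array([0.5, 2.0, -4.0])
        mean, var = tweedie_posterior(z, logf, s0sq)
        np.testing.assert_allclose(mean, z * s / (s0sq + s), rtol=1e-6)
        np.testing.assert_allclose(var, s0sq * s / (s0sq + s), rtol=1e-4)
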