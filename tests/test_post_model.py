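import numpy as np
import pytest
from scipy.stats import multivariate_normal

from cd4recovery.kernels import FbmParams, chol_psd, fbm_cov_matrix
from cd4recovery.links import LinkFunction, LinkSpec
from cd4recovery.params import PostParams, SharedParams
from cd4recovery.post_model import (
    asymptote_loading,
    half_life,
    post_conditional_cov,
    post_loglik_given_u,
    recovery_mean,
)

LOG_LOG2 = float(np.log(np.log(2.0)))


class TestRecoveryMean:
    def test_starts_at_baseline(self):
        assert recovery_mean(0.0, 15.0, 25.0, 0.3) == 15.0

    def test_half_life_worked_example(self):
        # half-life 1: halfway from 15 to 25 after one year
        assert recovery_mean(1.0, 15.0, 25.0, LOG_LOG2) == pytest.approx(20.0)

    def test_flat_when_baseline_equals_asymptote(self):
        for t in (0.0, 1.0, 10.0):
            assert recovery_mean(t, 25.0, 25.0, 0.0) == pytest.approx(25.0)

    def test_monotone_between_baseline_and_asymptote(self):
        t = np.linspace(0, 10, 50)
        g = recovery_mean(t, 15.0, 25.0, 0.0)
        assert np.all(np.diff(g) > 0) and g.max() < 25.0


class TestHalfLife:
    @pytest.mark.parametrize(
        "phi2,expected",
        [(LOG_LOG2, 1.0), (0.0, np.log(2.0)), (float(np.log(2 * np.log(2))), 0.5)],
    )
    def test_values(self, phi2, expected):
        assert half_life(phi2) == pytest.approx(expected, rel=1e-12)


class TestAsymptoteLoading:
    def test_limits(self):
        assert asymptote_loading(0.0, 0.3) == 0.0
        assert asymptote_loading(1e6, 0.3) == pytest.approx(1.0)
        assert asymptote_loading(1.0, LOG_LOG2) == pytest.approx(0.5)

    def test_linearity_in_tau_identity(self, rng):
        # g with asymptote phi1 + tau  ==  g with phi1, plus tau * c(t)
        t = rng.uniform(0, 5, 20)
        u, phi1, phi2, tau = 15.0, 24.0, -0.4, 1.7
        lhs = recovery_mean(t, u, phi1 + tau, phi2)
        rhs = recovery_mean(t, u, phi1, phi2) + tau * asymptote_loading(t, phi2)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-14)


@pytest.fixture
def post_params(model2_params):
    return model2_params.post


class TestConditionalCov:
    def test_single_obs_at_zero_is_pure_nugget(self, post_params):
        got = post_conditional_cov(np.array([0.0]), 0.0, post_params, SharedParams(1.3))
        np.testing.assert_allclose(got, [[1.3]])

    def test_no_random_terms_gives_nugget(self):
        post = PostParams(
            LinkFunction(LinkSpec()), LinkFunction(LinkSpec()), 0.0, FbmParams(1e-14, 0.5)
        )
        got = post_conditional_cov(np.array([1.0, 2.0]), 0.0, post, SharedParams(2.0))
        np.testing.assert_allclose(got, 2.0 * np.eye(2), atol=1e-12)

    def test_monte_carlo_oracle(self, rng, post_params):
        shared = SharedParams(1.0)
        t = np.array([0.7, 2.1])
        phi2 = -0.5
        n = 200_000
        tau = rng.normal(0, np.sqrt(post_params.p_var), n)
        L = chol_psd(fbm_cov_matrix(t, post_params.fbm))
        w = (L @ rng.standard_normal((2, n))).T
        e = rng.normal(0, 1.0, (n, 2))
        draws = tau[:, None] * asymptote_loading(t, phi2)[None, :] + w + e
        emp = np.cov(draws.T)
        expected = post_conditional_cov(t, phi2, post_params, shared)
        se = expected / np.sqrt(n / 3)
        np.testing.assert_allclose(emp, expected, atol=float(3 * np.abs(se).max()))


class TestPostLoglik:
    def test_univariate_mode(self, post_params):
        shared = SharedParams(1.0)
        u = 18.0
        t = np.array([1.2])
        phi1 = float(post_params.phi1(u, 1.0))
        phi2 = float(post_params.phi2(u, 1.0))
        y = np.array([recovery_mean(1.2, u, phi1, phi2)])
        v = post_conditional_cov(t, phi2, post_params, shared)[0, 0]
        got = post_loglik_given_u(y, t, u, 1.0, post_params, shared)
        assert got == pytest.approx(-0.5 * np.log(2 * np.pi * v))

    def test_truncation_makes_negative_u_equal_zero(self, post_params):
        shared = SharedParams(1.0)
        y, t = np.array([12.0, 16.0]), np.array([0.5, 2.0])
        a = post_loglik_given_u(y, t, -4.0, 1.0, post_params, shared)
        b = post_loglik_given_u(y, t, 0.0, 1.0, post_params, shared)
        assert a == pytest.approx(b, rel=1e-14)

    def test_against_dense_mvn_oracle(self, rng, post_params):
        shared = SharedParams(1.5)
        for _ in range(5):
            t = np.sort(rng.uniform(0.1, 4, 3))
            y = 18.0 + rng.normal(0, 3, 3)
            u, t_trt = float(rng.uniform(5, 25)), 1.0
            phi1 = float(post_params.phi1(u, t_trt))
            phi2 = float(post_params.phi2(u, t_trt))
            mean = recovery_mean(t, u, phi1, phi2)
            cov = post_conditional_cov(t, phi2, post_params, shared)
            expected = multivariate_normal.logpdf(y, mean, cov)
            got = post_loglik_given_u(y, t, u, t_trt, post_params, shared)
            assert got == pytest.approx(expected, rel=1e-10)

    def test_continuity_in_u_at_kink(self, post_params):
        shared = SharedParams(1.0)
        y, t = np.array([14.0]), np.array([1.0])
        eps = 1e-8
        left = post_loglik_given_u(y, t, -eps, 1.0, post_params, shared)
        right = post_loglik_given_u(y, t, eps, 1.0, post_params, shared)
        assert left == pytest.approx(right, abs=1e-5)

    def test_constant_link_nests_in_linear(self, model1_params, rng):
        # linear links with zero slopes reproduce the constant-link density
        from cd4recovery.modelspec import preset

        spec2 = preset("model2")
        post_lin = PostParams(
            LinkFunction(spec2.phi1_spec, (np.array([25.9, 0.0]),)),
            LinkFunction(spec2.phi2_spec, (np.array([-0.16, 0.0]),)),
            model1_params.post.p_var,
            model1_params.post.fbm,
        )
        shared = model1_params.shared
        t = np.sort(rng.uniform(0.1, 4, 4))
        y = 20.0 + rng.normal(0, 3, 4)
        for u in (3.0, 17.0, 28.0):
            a = post_loglik_given_u(y, t, u, 1.0, model1_params.post, shared)
            b = post_loglik_given_u(y, t, u, 1.0, post_lin, shared)
            assert a == pytest.approx(b, rel=1e-14)

    def test_empty_post_contributes_zero(self, post_params):
        got = post_loglik_given_u(np.array([]), np.array([]), 15.0, 1.0, post_params, SharedParams(1.0))
        assert got == 0.0
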