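import numpy as np
import pytest
from scipy.stats import kstest, norm, spearmanr

from cd4recovery.joint_likelihood import (
    CohortMatrix,
    cohort_loglik,
    cohort_loglik_gh,
    cohort_loglik_laplace,
    gamma_scaling_from_normal,
    subject_loglik_gh,
    subject_loglik_laplace,
)
from cd4recovery.latent_baseline import baseline_conditional
from cd4recovery.modelspec import ModelSpec, QuadratureConfig, preset
from cd4recovery.params import HeavyTailParams
from cd4recovery.post_model import post_loglik_given_u
from cd4recovery.pre_model import pre_loglik
from cd4recovery.data import SubjectRecord

from conftest import random_subject


def brute_force_loglik(sub, params, n_grid=20001, width=10.0):
    """Dense trapezoid integration of the marginal likelihood over u."""
    lp_pre = pre_loglik(sub.y_pre, sub.t_pre, params.pre, params.shared)
    law = baseline_conditional(
        sub.y_pre, sub.t_pre, sub.t_trt, params.pre, params.shared
    )
    sd = np.sqrt(law.v_prime)
    us = np.linspace(law.mu_prime - width * sd, law.mu_prime + width * sd, n_grid)
    vals = np.array(
        [
            post_loglik_given_u(
                sub.y_post, sub.t_post, u, sub.t_trt, params.post, params.shared
            )
            for u in us
        ]
    )
    logf = vals + norm.logpdf(us, law.mu_prime, sd)
    top = logf.max()
    return lp_pre + top + np.log(np.trapezoid(np.exp(logf - top), us))


class TestGammaScaling:
    def test_exponential_median(self):
        # v=2: gamma(1, 1) quantile at 1/2 is log 2
        assert gamma_scaling_from_normal(0.0, 2.0) == pytest.approx(np.log(2.0))

    def test_unit_mean(self, rng):
        z = rng.standard_normal(200_000)
        for v in (2.0, 4.0, 20.0):
            w = gamma_scaling_from_normal(z, v)
            assert np.mean(w) == pytest.approx(1.0, abs=0.02)

    def test_gaussian_limit(self):
        for z in (-3.0, 0.0, 3.0):
            assert gamma_scaling_from_normal(z, 1e8) == pytest.approx(1.0, abs=1e-3)

    def test_monotone_in_z(self):
        z = np.linspace(-8, 8, 100)
        w = gamma_scaling_from_normal(z, 4.0)
        assert np.all(np.diff(w) >= 0)

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            gamma_scaling_from_normal(0.0, 0.0)


class TestAdaptiveGH:
    def test_matches_trapezoid_oracle(self, rng, model2_params):
        for k in range(10):
            sub = random_subject(rng, model2_params, sid=f"s{k}")
            got = subject_loglik_gh(sub, model2_params)
            expected = brute_force_loglik(sub, model2_params)
            assert got == pytest.approx(expected, rel=1e-6)

    def test_no_post_data_reduces_to_pre_loglik(self, rng, model2_params):
        sub = random_subject(rng, model2_params, n_pre=3, n_post=1)
        sub_nopost = SubjectRecord(
            "x", sub.t_pre, sub.y_pre, np.array([]), np.array([]), sub.t_trt
        )
        cm = CohortMatrix([sub_nopost], validate=False)
        spec = preset("model2")
        got = cohort_loglik_gh(cm, model2_params, spec)
        expected = pre_loglik(sub.y_pre, sub.t_pre, model2_params.pre, model2_params.shared)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_degenerate_baseline_law_is_plugin_density(self, model2_params):
        # a noiseless observation essentially at the treatment time pins u,
        # so the integral collapses to the conditional density at mu'
        params = model2_params.copy()
        params.shared.sigma2 = 1e-8
        t_trt = 1.0
        sub = SubjectRecord(
            "s", np.array([t_trt - 1e-9]), np.array([19.0]),
            np.array([0.5, 1.5]), np.array([20.0, 22.0]), t_trt,
        )
        law = baseline_conditional(sub.y_pre, sub.t_pre, t_trt, params.pre, params.shared)
        # the fBM increment over the tiny gap keeps v' small but nonzero
        assert law.v_prime < 1e-4
        got = subject_loglik_gh(sub, params)
        expected = pre_loglik(sub.y_pre, sub.t_pre, params.pre, params.shared) + (
            post_loglik_given_u(
                sub.y_post, sub.t_post, law.mu_prime, t_trt, params.post, params.shared
            )
        )
        assert got == pytest.approx(expected, rel=1e-4)

    def test_node_count_convergence(self, rng, model2_params):
        for k in range(6):
            sub = random_subject(rng, model2_params, n_pre=int(rng.integers(2, 5)), sid=f"c{k}")
            a = subject_loglik_gh(sub, model2_params, QuadratureConfig(15))
            b = subject_loglik_gh(sub, model2_params, QuadratureConfig(41))
            assert abs(a - b) < 1e-6

    def test_adaptivity_required_on_diffuse_case(self, rng, model2_params):
        # a subject with no pre data has a diffuse baseline prior; the
        # recentred rule is far more accurate than the uncentred one
        sub = random_subject(rng, model2_params, n_pre=0, n_post=3)
        sub = SubjectRecord("d", np.array([]), np.array([]), sub.t_post, sub.y_post, sub.t_trt)
        truth = subject_loglik_gh(sub, model2_params, QuadratureConfig(101))
        adaptive = subject_loglik_gh(sub, model2_params, QuadratureConfig(15, recenter=True))
        plain = subject_loglik_gh(sub, model2_params, QuadratureConfig(15, recenter=False))
        assert abs(adaptive - truth) < abs(plain - truth)
        assert abs(adaptive - truth) < 1e-3

    def test_fast_and_reference_paths_agree(self, rng, model2_params):
        subs = [random_subject(rng, model2_params, sid=f"p{k}") for k in range(25)]
        cm = CohortMatrix(subs)
        spec = preset("model2")
        a = cohort_loglik_gh(cm, model2_params, spec, use_fast=True)
        b = cohort_loglik_gh(cm, model2_params, spec, use_fast=False)
        assert a == pytest.approx(b, abs=1e-6)

    def test_location_equivariance(self, rng, model2_params):
        # adding a constant c to every observation, beta0 + c, and shifting
        # the link coefficients accordingly leaves the likelihood unchanged
        # (the u+ kink is immaterial when u stays far above zero)
        c = 5.0
        params = model2_params.copy()
        shifted = model2_params.copy()
        shifted.pre.beta0 += c
        a1, a2 = shifted.post.phi1.coeffs[0]
        shifted.post.phi1.coeffs[0][0] = a1 + c * (1.0 - a2)
        b1, b2 = shifted.post.phi2.coeffs[0]
        shifted.post.phi2.coeffs[0][0] = b1 - c * b2
        for k in range(5):
            sub = random_subject(rng, params, sid=f"e{k}")
            sub_shift = SubjectRecord(
                sub.subject_id, sub.t_pre, sub.y_pre + c, sub.t_post, sub.y_post + c, sub.t_trt
            )
            assert subject_loglik_gh(sub_shift, shifted) == pytest.approx(
                subject_loglik_gh(sub, params), rel=1e-6
            )


class TestCohortLoglik:
    def test_empty_cohort(self, model2_params):
        assert cohort_loglik([], model2_params, preset("model2")) == 0.0

    def test_order_invariance_and_duplication(self, rng, model2_params):
        subs = [random_subject(rng, model2_params, sid=f"o{k}") for k in range(6)]
        spec = preset("model2")
        a = cohort_loglik(subs, model2_params, spec)
        b = cohort_loglik(subs[::-1], model2_params, spec)
        assert a == pytest.approx(b, rel=1e-10)
        twice = cohort_loglik(subs + subs, model2_params, spec)
        assert twice == pytest.approx(2 * a, rel=1e-10)

    def test_unsupported_extensions_raise(self, model2_params):
        from cd4recovery.modelspec import UnsupportedModelError

        spec = preset("model2", random_phi2=True)
        with pytest.raises(UnsupportedModelError):
            cohort_loglik([], model2_params, spec)


class TestHeavyTails:
    def test_gaussian_limit_matches_gh(self, rng, model2_params):
        params = model2_params.copy()
        params.heavy = HeavyTailParams(1e6, 1e6, 0.0)
        for k in range(5):
            sub = random_subject(rng, model2_params, sid=f"h{k}")
            heavy = subject_loglik_laplace(sub, params)
            gauss = subject_loglik_gh(sub, model2_params)
            assert heavy == pytest.approx(gauss, abs=1e-3)

    def test_zero_copula_correlation_factorises_prior(self):
        # the (a, b) prior at rho = 0 is the product of standard normals
        from cd4recovery.joint_likelihood import _LOG_2PI

        rho = 0.0
        a, b = 0.7, -1.2
        lp_ab = (
            -_LOG_2PI
            - 0.5 * np.log1p(-(rho**2))
            - (a**2 - 2 * rho * a * b + b**2) / (2 * (1 - rho**2))
        )
        assert lp_ab == pytest.approx(norm.logpdf(a) + norm.logpdf(b), rel=1e-14)

    def test_single_node_rule_is_laplace(self, rng, model2_params):
        # one-point adaptive GH equals the Laplace approximation in u; it
        # should track the full quadrature within a loose tolerance
        for k in range(5):
            sub = random_subject(rng, model2_params, n_pre=int(rng.integers(2, 5)), sid=f"l{k}")
            lap = subject_loglik_gh(sub, model2_params, QuadratureConfig(1))
            gh = subject_loglik_gh(sub, model2_params, QuadratureConfig(15))
            assert lap == pytest.approx(gh, abs=0.05)

    def test_moran_copula_marginals_and_rank_correlation(self, rng):
        n = 200_000
        v1, v2 = 3.84, 4.28
        rhos = [-0.5, 0.0, 0.5]
        rank_corrs = []
        for rho in rhos:
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
            w1 = gamma_scaling_from_normal(z[:, 0], v1)
            w2 = gamma_scaling_from_normal(z[:, 1], v2)
            rank_corrs.append(spearmanr(w1, w2).statistic)
        # marginals at rho=0.5 follow the gamma(v/2, v/2) law
        assert kstest(w1, "gamma", args=(v1 / 2, 0, 2 / v1)).pvalue > 0.01
        assert kstest(w2, "gamma", args=(v2 / 2, 0, 2 / v2)).pvalue > 0.01
        assert rank_corrs[0] < rank_corrs[1] < rank_corrs[2]

    def test_heavy_requires_heavy_params(self, rng, model2_params):
        sub = random_subject(rng, model2_params)
        with pytest.raises(ValueError):
            subject_loglik_laplace(sub, model2_params)
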