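import numpy as np
import pytest

from cd4recovery import fit, load_fit, save_fit
from cd4recovery.estimation import (
    _TRANSFORMS,
    bic,
    lrt,
    pack_params,
    param_entries,
    predict_band,
    subject_posterior_modes,
    unpack_params,
    wald_cis,
)
from cd4recovery.joint_likelihood import CohortMatrix, cohort_loglik
from cd4recovery.modelspec import preset
from cd4recovery.synthetic import SimulationConfig, model1_truth, model4_truth, simulate_cohort


class TestTransforms:
    @pytest.mark.parametrize("name,values", [
        ("identity", [-3.0, 0.0, 5.2]),
        ("log", [1e-6, 1.0, 47.3]),
        ("logit", [0.01, 0.5, 0.99]),
        ("corr", [-0.999, 0.0, 0.95]),
    ])
    def test_round_trip(self, name, values):
        fwd, inv = _TRANSFORMS[name]
        for x in values:
            assert inv(fwd(x)) == pytest.approx(x, abs=1e-12)

    def test_parameter_set_round_trip(self):
        spec = preset("model4")
        truth = model4_truth()
        entries = param_entries(spec)
        theta = pack_params(truth, entries)
        back = unpack_params(theta, truth, entries)
        theta2 = pack_params(back, entries)
        np.testing.assert_allclose(theta, theta2, atol=1e-12)

    def test_entry_count_matches_model_ladder(self):
        # the standard ladder of variants has 13/15/19/23/27/26 parameters
        for name, k in [("model1", 13), ("model2", 15), ("model3", 19),
                        ("model4", 23), ("model5", 27), ("model6", 26)]:
            assert len(param_entries(preset(name))) == k
            assert preset(name).n_params() == k


class TestLrtBic:
    def test_published_delta2l_values(self):
        d, p = lrt(-31954.8, -31724.6, 2)
        assert d == pytest.approx(460.4, abs=1e-9)
        assert p < 1e-4
        d, _ = lrt(-31724.6, -31708.9, 4)
        assert d == pytest.approx(31.4, abs=1e-9)
        d, p = lrt(-31664.5, -31656.5, 4)
        assert d == pytest.approx(16.0, abs=1e-9)
        assert p == pytest.approx(0.003, abs=5e-4)

    def test_identical_logliks(self):
        assert lrt(-10.0, -10.0, 1) == (0.0, 1.0)

    def test_chi2_pvalue_for_small_delta(self):
        _, p = lrt(-100.3, -100.0, 1)
        assert p == pytest.approx(0.44, abs=0.01)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            lrt(-10.0, -11.0, 1)

    def test_bic_published_arithmetic(self):
        assert bic(-31954.8, 13, 13107) == pytest.approx(64032.85, abs=0.005)
        assert bic(-31724.6, 15, 13107) == pytest.approx(63591.41, abs=0.005)
        assert bic(-12.5, 0, 100) == pytest.approx(25.0)

    def test_bic_needs_observations(self):
        with pytest.raises(ValueError):
            bic(-1.0, 2, 0)


@pytest.fixture(scope="module")
def small_fit():
    truth = model1_truth()
    cfg = SimulationConfig(n_subjects=40, truth=truth, spec=preset("model1"), seed=7)
    subs, _, _ = simulate_cohort(cfg)
    res = fit(subs, preset("model1"), init=truth, gradient="forward", ftol=1e-10)
    return subs, truth, res


class TestFit:
    def test_converged_with_pd_information(self, small_fit):
        _, _, res = small_fit
        assert res.converged
        assert res.info_pd
        assert res.n_params == 13

    def test_refit_at_optimum_is_fixed_point(self, small_fit):
        subs, _, res = small_fit
        res2 = fit(subs, preset("model1"), init=res.params_hat,
                   gradient="forward", compute_ci=False, ftol=1e-10)
        assert res2.loglik == pytest.approx(res.loglik, abs=5e-3)

    def test_nested_spec_with_zero_extras_gives_same_loglik(self, small_fit):
        subs, _, res = small_fit
        spec2 = preset("model2")
        params2 = spec2.template_params(res.params_hat)
        ll1 = cohort_loglik(subs, res.params_hat, preset("model1"))
        ll2 = cohort_loglik(subs, params2, spec2)
        assert ll1 == pytest.approx(res.loglik, abs=1e-6)
        assert ll2 == pytest.approx(ll1, abs=1e-6)

    def test_wald_intervals_shapes(self, small_fit):
        _, _, res = small_fit
        cis = wald_cis(res)
        lo, mid, hi = cis["beta0"]
        assert lo < mid < hi
        # identity transform: symmetric interval
        assert (mid - lo) == pytest.approx(hi - mid, rel=1e-6)
        # log transform: positive and asymmetric
        lo, mid, hi = cis["sigma2"]
        assert lo > 0
        # correlation stays inside (-1, 1)
        lo, _, hi = cis["rho"]
        assert -1 <= lo < hi <= 1

    def test_result_roundtrip_reproduces_loglik(self, small_fit, tmp_path):
        subs, _, res = small_fit
        path = tmp_path / "fit.json"
        save_fit(res, path)
        back = load_fit(path)
        ll = cohort_loglik(subs, back.params_hat, back.spec)
        assert ll == pytest.approx(back.loglik, abs=1e-8)
        assert back.n_params == res.n_params

    def test_unsupported_extension_raises(self, small_fit):
        from cd4recovery.modelspec import UnsupportedModelError

        subs, _, _ = small_fit
        with pytest.raises(UnsupportedModelError):
            fit(subs, preset("model2", pre_slope_effect=True))


class TestPosteriorModes:
    def test_no_post_data_mode_is_prior_mean(self, model2_params, rng):
        from cd4recovery.data import SubjectRecord
        from cd4recovery.latent_baseline import baseline_conditional

        t_pre = np.linspace(0.1, 1.8, 6)
        y_pre = 22.0 - 1.4 * t_pre + rng.normal(0, 1, 6)
        sub = SubjectRecord("s", t_pre, y_pre, np.array([]), np.array([]), 2.0)
        cm = CohortMatrix([sub], validate=False)
        terms = subject_posterior_modes(model2_params, cm, preset("model2"))
        law = baseline_conditional(y_pre, t_pre, 2.0, model2_params.pre, model2_params.shared)
        assert terms["u_hat"][0] == pytest.approx(law.mu_prime, abs=1e-8)
        assert terms["u_sd"][0] == pytest.approx(np.sqrt(law.v_prime), rel=1e-6)

    def test_modes_track_true_latents(self):
        truth = model4_truth()
        cfg = SimulationConfig(n_subjects=150, seed=21)
        subs, lat, _ = simulate_cohort(cfg)
        terms = subject_posterior_modes(truth, CohortMatrix(subs), preset("model4"))
        u_hat = np.asarray(terms["u_hat"])
        u_true = lat.set_index("subject_id").loc[terms["subject_id"], "u"].to_numpy()
        assert np.corrcoef(u_hat, u_true)[0, 1] > 0.9


class TestPredictBand:
    def test_band_at_zero_is_measurement_error_only(self, model2_params):
        band = predict_band(model2_params, 15.0, 1.0, np.array([0.0]))
        z = 1.6448536269514722  # 90% two-sided
        sd = np.sqrt(model2_params.shared.sigma2)
        assert band["lower"][0] == pytest.approx((15.0 - z * sd) ** 2, rel=1e-6)
        assert band["upper"][0] == pytest.approx((15.0 + z * sd) ** 2, rel=1e-6)

    def test_zero_coverage_collapses_to_mean_curve(self, model2_params):
        t = np.linspace(0, 4, 9)
        band = predict_band(model2_params, 15.0, 1.0, t, coverage=0.0)
        np.testing.assert_allclose(band["lower"], band["mean"], rtol=1e-10)
        np.testing.assert_allclose(band["upper"], band["mean"], rtol=1e-10)

    def test_band_symmetric_on_analysis_scale(self, model2_params):
        t = np.array([30.0])  # effectively at the asymptote
        band = predict_band(model2_params, 15.0, 1.0, t, include_measurement_error=False)
        m = band["mean_sqrt_scale"][0]
        lo, hi = np.sqrt(band["lower"][0]), np.sqrt(band["upper"][0])
        assert (m - lo) == pytest.approx(hi - m, rel=1e-6)

    def test_invalid_inputs(self, model2_params):
        with pytest.raises(ValueError):
            predict_band(model2_params, -1.0, 1.0, np.array([0.0]))
        with pytest.raises(ValueError):
            predict_band(model2_params, 1.0, 1.0, np.array([-0.5]))


def test_heavy_tail_fit_recovers_finite_df():
    """Scaled-down closure check: maximising the heavy-tail block (degrees
    of freedom and copula correlation, other parameters profiled at truth)
    on heavy-tailed data yields finite, moderate df estimates -- the
    Gaussian model corresponds to df = +inf."""
    from scipy import optimize

    from cd4recovery.params import HeavyTailParams
    from cd4recovery.synthetic import model6_truth

    truth = model6_truth()
    spec = preset("model6")
    cfg = SimulationConfig(n_subjects=30, truth=truth, spec=spec, seed=5)
    subs, _, _ = simulate_cohort(cfg)
    cm = CohortMatrix(subs)
    from cd4recovery.joint_likelihood import cohort_loglik_laplace

    def negll(theta):
        ps = truth.copy()
        ps.heavy = HeavyTailParams(np.exp(theta[0]), np.exp(theta[1]), np.tanh(theta[2]))
        return -cohort_loglik_laplace(cm, ps, spec)

    res = optimize.minimize(
        negll, np.array([np.log(8.0), np.log(8.0), 0.0]),
        method="Nelder-Mead", options={"maxiter": 60, "xatol": 0.05, "fatol": 0.05},
    )
    df_pre, df_post = np.exp(res.x[0]), np.exp(res.x[1])
    assert np.isfinite(df_pre) and np.isfinite(df_post)
    assert df_pre < 20.0 and df_post < 20.0
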