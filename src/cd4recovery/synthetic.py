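"""Synthetic cohorts with the full generative structure of the model.

The generator emulates an observational seroconverter cohort measured on
the square-root CD4 scale: irregular visit times (gamma-distributed gaps,
mean 0.25 y), a heavy-tailed distribution of time from seroconversion to
treatment initiation (log-normal, median 1.3 y), a small fraction of
subjects with no pre-treatment measurements, and per-subject trajectories
drawn from the exact stochastic structure the model assumes: random
intercept/slope, pre-phase fBM (jointly with its value at treatment
initiation, by Cholesky factorisation of the joint kernel matrix, so the
latent baseline is consistent with the observed path), measurement error,
random asymptote, post-phase fBM, and optionally the Moran-copula gamma
scaling pair.

Treatment initiation can instead be triggered by the *observed* series
crossing a threshold (default sqrt(350) on the square-root scale), the
mechanism that biases the last observed pre-treatment value below the true
baseline and motivates the latent-baseline treatment of u.

Latent truth (b, u, tau, w1, w2 and the process paths) is always returned
alongside the observed records so that simulation-based tests never have
to re-derive latents from seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SubjectRecord
from .joint_likelihood import gamma_scaling_from_normal
from .kernels import FbmParams, chol_psd, fbm_cov_matrix
from .links import LinkFunction
from .modelspec import ModelSpec, preset
from .params import (
    HeavyTailParams,
    ParameterSet,
    PostParams,
    PreParams,
    SharedParams,
)
from .post_model import recovery_mean

__all__ = [
    "SimulationConfig",
    "model4_truth",
    "model1_truth",
    "model2_like_truth",
    "model6_truth",
    "simulate_subject",
    "simulate_cohort",
    "bias_report",
]


def model4_truth() -> ParameterSet:
    """Stratified linear-link Gaussian truth (typical published magnitudes)."""
    spec = preset("model4")
    return ParameterSet(
        pre=PreParams(22.26, -1.30, 14.43, 0.20, -0.95, FbmParams(5.99, 0.31)),
        post=PostParams(
            LinkFunction(
                spec.phi1_spec,
                (np.array([7.04, 0.90]), np.array([10.73, 0.67]), np.array([14.58, 0.55])),
            ),
            LinkFunction(
                spec.phi2_spec,
                (np.array([2.66, 0.02]), np.array([-0.99, 0.15]), np.array([-3.64, 0.23])),
            ),
            3.07,
            FbmParams(3.36, 0.38),
        ),
        shared=SharedParams(1.92**2),
    )


def model1_truth() -> ParameterSet:
    """Constant-link Gaussian truth."""
    spec = preset("model1")
    return ParameterSet(
        pre=PreParams(22.44, -1.36, 12.37, 0.55, -0.65, FbmParams(9.68, 0.11)),
        post=PostParams(
            LinkFunction(spec.phi1_spec, (np.array([25.93]),)),
            LinkFunction(spec.phi2_spec, (np.array([-0.16]),)),
            11.09,
            FbmParams(7.59, 0.08),
        ),
        shared=SharedParams(1.25**2),
    )


def model2_like_truth() -> ParameterSet:
    """Unstratified linear-link Gaussian truth."""
    spec = preset("model2")
    return ParameterSet(
        pre=PreParams(22.45, -1.39, 13.39, 0.25, -0.86, FbmParams(5.91, 0.30)),
        post=PostParams(
            LinkFunction(spec.phi1_spec, (np.array([11.42, 0.69]),)),
            LinkFunction(spec.phi2_spec, (np.array([-3.34, 0.24]),)),
            2.97,
            FbmParams(3.09, 0.42),
        ),
        shared=SharedParams(1.95**2),
    )


def model6_truth() -> ParameterSet:
    """Heavy-tailed stratified truth (Moran-copula scaling variables)."""
    spec = preset("model6")
    return ParameterSet(
        pre=PreParams(22.23, -1.36, 12.92, 0.49, -0.63, FbmParams(5.37, 0.16)),
        post=PostParams(
            LinkFunction(
                spec.phi1_spec,
                (np.array([8.44, 0.84]), np.array([12.32, 0.64]), np.array([14.35, 0.57])),
            ),
            LinkFunction(
                spec.phi2_spec,
                (np.array([5.68, -0.14]), np.array([0.23, 0.01]), np.array([-2.25, 0.13])),
            ),
            2.72,
            FbmParams(4.33, 0.13),
        ),
        shared=SharedParams(1.32**2),
        heavy=HeavyTailParams(3.84, 4.28, 0.37),
    )


@dataclass
class SimulationConfig:
    """Generative settings for a synthetic cohort.

    Defaults emulate the shape of a UK seroconverter-type cohort: about
    five pre- and six post-treatment measurements per subject at the
    median, a 39/852 fraction of subjects with no pre-treatment data, and
    treatment times with median about 1.3 years from seroconversion.
    """

    n_subjects: int = 852
    truth: ParameterSet = field(default_factory=model4_truth)
    spec: ModelSpec = field(default_factory=lambda: preset("model4"))
    gap_mean_pre: float = 0.30      # mean inter-visit gap before treatment, years
    gap_mean_post: float = 0.25     # mean inter-visit gap after treatment, years
    gap_shape: float = 2.0          # gamma shape of the gaps
    entry_visit_time: float = 0.02  # first pre visit (measurement at cohort entry)
    treatment_rule: str = "fixed"   # "fixed" or "threshold"
    t_trt_log_mean: float = float(np.log(1.3))
    t_trt_log_sd: float = 1.14      # matches a 0.6-2.8 y interquartile range
    threshold: float = float(np.sqrt(350.0))
    threshold_delay: tuple[float, float] = (0.04, 0.12)  # treatment start lag, years
    fraction_no_pre: float = 39.0 / 852.0
    followup_log_mean: float = float(np.log(1.5))
    followup_log_sd: float = 0.8
    max_followup: float = 8.0
    max_pre_followup: float = 10.0  # threshold rule: treat at this time regardless
    seed: int | None = None
    # fixed visit schedule overrides (for moment-matching tests)
    fixed_pre_times: tuple[float, ...] | None = None
    fixed_post_times: tuple[float, ...] | None = None
    fixed_t_trt: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_no_pre <= 1.0:
            raise ValueError("fraction_no_pre must be a probability")
        if self.gap_mean_pre <= 0 or self.gap_mean_post <= 0 or self.gap_shape <= 0:
            raise ValueError("visit gaps must have positive mean and shape")
        if self.treatment_rule not in ("fixed", "threshold"):
            raise ValueError("treatment_rule must be 'fixed' or 'threshold'")


def _draw_gaps(rng, config, t_max, gap_mean, start=0.0):
    times = []
    total = start
    scale = gap_mean / config.gap_shape
    if start > 0 and start < t_max:
        times.append(start)
    while True:
        total += rng.gamma(config.gap_shape, scale)
        if total >= t_max:
            return np.array(times)
        times.append(total)


def _conditional_process_draw(rng, t_new, t_obs, w_obs, fbm, w_scale):
    """Draw W(t_new) | W(t_obs) = w_obs for the scaled fBM kernel."""
    k_new = fbm.kappa * t_new ** (2 * fbm.hurst) / w_scale
    if len(t_obs) == 0:
        return rng.normal(0.0, np.sqrt(max(k_new, 0.0)))
    K = fbm_cov_matrix(np.asarray(t_obs), fbm) / w_scale
    K[np.diag_indices_from(K)] += 1e-10
    k_vec = fbm_cov_matrix(np.append(t_obs, t_new), fbm)[-1, :-1] / w_scale
    sol = np.linalg.solve(K, np.column_stack([w_obs, k_vec]))
    mean = float(k_vec @ sol[:, 0])
    var = max(k_new - float(k_vec @ sol[:, 1]), 0.0)
    return mean + rng.normal(0.0, np.sqrt(var))


def simulate_subject(config: SimulationConfig, rng, subject_id: str = "s0") -> SubjectRecord:
    """Simulate one subject; the record carries its latent truth.

    The pre-phase process is drawn jointly at the visit times *and* the
    treatment time, so the latent baseline is exactly consistent with the
    observed path.
    """
    truth = config.truth
    pre, post, shared = truth.pre, truth.post, truth.shared
    sigma = np.sqrt(shared.sigma2)

    psi = pre.psi()
    if psi[0, 0] > 0 or psi[1, 1] > 0:
        b = chol_psd(psi + 1e-12 * np.eye(2)) @ rng.standard_normal(2)
    else:
        b = np.zeros(2)
    if truth.heavy is not None:
        heavy = truth.heavy
        cov = np.array([[1.0, heavy.rho_moran], [heavy.rho_moran, 1.0]])
        a_b = rng.multivariate_normal(np.zeros(2), cov, method="cholesky")
        w1 = float(gamma_scaling_from_normal(a_b[0], heavy.v_pre))
        w2 = float(gamma_scaling_from_normal(a_b[1], heavy.v_post))
    else:
        w1 = w2 = 1.0

    no_pre = rng.uniform() < config.fraction_no_pre

    if config.treatment_rule == "threshold" and config.fixed_t_trt is None:
        t_obs: list[float] = []
        w_path: list[float] = []
        y_vals: list[float] = []
        t = 0.0
        scale = config.gap_mean_pre / config.gap_shape
        first = True
        while True:
            t = config.entry_visit_time if first else t + rng.gamma(config.gap_shape, scale)
            first = False
            if t >= config.max_pre_followup:
                t_trt = config.max_pre_followup
                break
            w_new = _conditional_process_draw(rng, t, t_obs, w_path, pre.fbm, w1)
            y = pre.beta0 + pre.beta1 * t + b[0] + b[1] * t + w_new + rng.normal(0, sigma)
            t_obs.append(t)
            w_path.append(w_new)
            y_vals.append(y)
            if y < config.threshold:
                t_trt = t + rng.uniform(*config.threshold_delay)
                break
        w_trt = _conditional_process_draw(rng, t_trt, t_obs, w_path, pre.fbm, w1)
        t_pre = np.array(t_obs)
        y_pre = np.array(y_vals)
        if no_pre:
            t_pre = np.empty(0)
            y_pre = np.empty(0)
    else:
        if config.fixed_t_trt is not None:
            t_trt = float(config.fixed_t_trt)
        else:
            t_trt = float(
                np.clip(rng.lognormal(config.t_trt_log_mean, config.t_trt_log_sd), 0.05, 8.0)
            )
        if no_pre:
            t_pre = np.empty(0)
        elif config.fixed_pre_times is not None:
            t_pre = np.asarray(config.fixed_pre_times, dtype=float)
        else:
            t_pre = _draw_gaps(rng, config, t_trt, config.gap_mean_pre, start=config.entry_visit_time)
        joint_t = np.append(t_pre, t_trt)
        L = chol_psd(fbm_cov_matrix(joint_t, pre.fbm) / w1 + 1e-12 * np.eye(joint_t.size))
        w_all = L @ rng.standard_normal(joint_t.size)
        w_trt = float(w_all[-1])
        y_pre = (
            pre.beta0 + pre.beta1 * t_pre + b[0] + b[1] * t_pre + w_all[:-1]
            + rng.normal(0, sigma, t_pre.size)
        )

    u = pre.beta0 + pre.beta1 * t_trt + b[0] + b[1] * t_trt + w_trt
    u_plus = max(0.0, u)
    tau = rng.normal(0.0, np.sqrt(post.p_var))
    phi1 = float(post.phi1(u_plus, t_trt)) + tau
    phi2 = float(post.phi2(u_plus, t_trt))

    if config.fixed_post_times is not None:
        t_post = np.asarray(config.fixed_post_times, dtype=float)
    else:
        fup = float(
            np.clip(
                rng.lognormal(config.followup_log_mean, config.followup_log_sd),
                0.1,
                config.max_followup,
            )
        )
        t_post = _draw_gaps(rng, config, fup, config.gap_mean_post)
    if t_post.size:
        L = chol_psd(fbm_cov_matrix(t_post, post.fbm) / w2 + 1e-12 * np.eye(t_post.size))
        w_post = L @ rng.standard_normal(t_post.size)
    else:
        w_post = np.empty(0)
    y_post = (
        recovery_mean(t_post, u_plus, phi1, phi2) + w_post
        + rng.normal(0, sigma, t_post.size)
    )

    latents = {
        "b0": float(b[0]),
        "b1": float(b[1]),
        "u": float(u),
        "tau": float(tau),
        "w1": w1,
        "w2": w2,
        "w_trt": float(w_trt),
        "w_pre_path": np.asarray(w_path if config.treatment_rule == "threshold" and config.fixed_t_trt is None else (w_all[:-1] if t_pre.size else np.empty(0))),
        "w_post_path": np.asarray(w_post),
    }
    return SubjectRecord(subject_id, t_pre, y_pre, t_post, y_post, t_trt, latents=latents)


def simulate_cohort(config: SimulationConfig, rng=None):
    """Simulate a cohort; subjects without post data are redrawn.

    Returns ``(subjects, latent_table, summary)`` where ``latent_table``
    is a tidy DataFrame of the per-subject latent truth and ``summary``
    reports the realised cohort shape (observation counts, fraction with
    no pre-treatment data).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    subjects = []
    for i in range(config.n_subjects):
        for _attempt in range(200):
            rec = simulate_subject(config, rng, subject_id=f"s{i:05d}")
            if rec.n_post >= 1:
                break
        else:
            raise RuntimeError("failed to draw a subject with post-treatment data")
        subjects.append(rec)
    rows = []
    for rec in subjects:
        row = {k: v for k, v in rec.latents.items() if np.ndim(v) == 0}
        row["subject_id"] = rec.subject_id
        row["t_trt"] = rec.t_trt
        row["n_pre"] = rec.n_pre
        row["n_post"] = rec.n_post
        rows.append(row)
    latent_table = pd.DataFrame(rows)
    n_pre = np.array([r.n_pre for r in subjects], dtype=int)
    n_post = np.array([r.n_post for r in subjects], dtype=int)
    summary = {
        "n_subjects": len(subjects),
        "total_pre_obs": int(n_pre.sum()),
        "total_post_obs": int(n_post.sum()),
        "median_pre_obs": float(np.median(n_pre)) if len(subjects) else 0.0,
        "median_post_obs": float(np.median(n_post)) if len(subjects) else 0.0,
        "fraction_no_pre": float((n_pre == 0).mean()) if len(subjects) else 0.0,
    }
    return subjects, latent_table, summary


def bias_report(subjects, latent_table: pd.DataFrame) -> dict:
    """Distribution of (last observed pre value - true baseline).

    Under threshold-triggered treatment the last observed value sits below
    the true baseline on average (regression to the mean at the triggering
    visit); under purely time-driven treatment the median difference is
    near zero.  Differences are reported on the analysis (square-root)
    scale and back-transformed to the measurement scale.
    """
    u_by_id = dict(zip(latent_table["subject_id"], latent_table["u"]))
    diffs, diffs_raw = [], []
    for rec in subjects:
        if rec.n_pre == 0:
            continue
        last = float(rec.y_pre[-1])
        u = float(u_by_id[rec.subject_id])
        diffs.append(last - u)
        diffs_raw.append(np.sign(last) * last**2 - np.sign(u) * u**2)
    diffs = np.asarray(diffs)
    diffs_raw = np.asarray(diffs_raw)
    qs = [0.25, 0.5, 0.75]
    return {
        "n": int(diffs.size),
        "median_analysis_scale": float(np.median(diffs)) if diffs.size else np.nan,
        "quartiles_analysis_scale": [float(q) for q in np.quantile(diffs, qs)] if diffs.size else [],
        "median_measurement_scale": float(np.median(diffs_raw)) if diffs_raw.size else np.nan,
        "fraction_below_truth": float((diffs < 0).mean()) if diffs.size else np.nan,
    }
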