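"""Asymptotic recovery model for the post-treatment phase.

Conditional on the truncated baseline u+, the mean recovery curve is the
asymptotic-regression ("monomolecular") form

    g(t, u+) = phi1 + (u+ - phi1) * exp(-exp(phi2) * t),

rising (or falling) from u+ at t = 0 towards the horizontal asymptote phi1
with rate exp(phi2); the half-life of the transition is
``log(2) / exp(phi2)``.  phi1 gains a subject-specific normal deviation
tau ~ N(0, P).  Because g is *linear* in tau,

    g(t, u+, phi1 + tau) = g(t, u+, phi1) + tau * c(t),
    c(t) = 1 - exp(-exp(phi2) * t),

tau can be marginalised analytically as a rank-one covariance update
rather than handled by quadrature.  The full conditional model is

    y_post | u ~ MVN( g(t_post, u+), P c c' + Sigma_post / w2 + sigma^2 I ),

where Sigma_post is a new post-phase fBM started at zero at treatment
initiation (independent of the pre-phase process given the scaling
variables) and w2 is the post-phase gamma scaling (1 in the Gaussian
model).
"""

from __future__ import annotations

import numpy as np

from .latent_baseline import truncate_baseline
from .kernels import fbm_cov_matrix
from .params import PostParams, SharedParams
from .pre_model import mvn_loglik

__all__ = [
    "recovery_mean",
    "half_life",
    "asymptote_loading",
    "post_conditional_cov",
    "post_loglik_given_u",
]


def recovery_mean(t_post, u_plus, phi1, phi2):
    """Mean recovery curve g(t, u+); exact u+ at t = 0, asymptote phi1."""
    t_post = np.asarray(t_post, dtype=float)
    if np.any(t_post < 0):
        raise ValueError("t_post must be >= 0")
    out = phi1 + (u_plus - phi1) * np.exp(-np.exp(phi2) * t_post)
    return out if out.ndim else float(out)


def half_life(phi2: float) -> float:
    """Years to cover half the distance from baseline to asymptote."""
    return float(np.log(2.0) / np.exp(phi2))


def asymptote_loading(t_post, phi2):
    """Coefficient of tau in g: ``c(t) = 1 - exp(-exp(phi2) t)`` in [0, 1)."""
    t_post = np.asarray(t_post, dtype=float)
    if np.any(t_post < 0):
        raise ValueError("t_post must be >= 0")
    out = 1.0 - np.exp(-np.exp(phi2) * t_post)
    return out if out.ndim else float(out)


def post_conditional_cov(
    t_post: np.ndarray,
    phi2: float,
    post: PostParams,
    shared: SharedParams,
    w2: float = 1.0,
) -> np.ndarray:
    """Covariance ``P c c' + Sigma_post / w2 + sigma^2 I`` of y_post | u."""
    if not w2 > 0:
        raise ValueError("w2 must be > 0")
    t_post = np.asarray(t_post, dtype=float)
    c = np.asarray(asymptote_loading(t_post, phi2))
    V = post.p_var * np.outer(c, c) + fbm_cov_matrix(t_post, post.fbm) / w2
    V[np.diag_indices_from(V)] += shared.sigma2
    return V


def post_loglik_given_u(
    y_post: np.ndarray,
    t_post: np.ndarray,
    u: float,
    t_trt: float,
    post: PostParams,
    shared: SharedParams,
    w2: float = 1.0,
    subject_id: str = "",
) -> float:
    """Closed-form MVN log-density of y_post given the latent baseline u.

    phi1 and phi2 are evaluated through the link functions at
    ``u+ = max(0, u)`` and the subject's treatment-timing stratum; tau is
    marginalised into the covariance.  Empty y_post contributes 0.
    """
    y_post = np.asarray(y_post, dtype=float)
    t_post = np.asarray(t_post, dtype=float)
    if y_post.size != t_post.size:
        raise ValueError("y_post and t_post must have equal length")
    if y_post.size == 0:
        return 0.0
    u_plus = truncate_baseline(u)
    phi1 = float(post.phi1(u_plus, t_trt))
    phi2 = float(post.phi2(u_plus, t_trt))
    mean = recovery_mean(t_post, u_plus, phi1, phi2)
    cov = post_conditional_cov(t_post, phi2, post, shared, w2)
    return mvn_loglik(y_post, mean, cov, context=subject_id)
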