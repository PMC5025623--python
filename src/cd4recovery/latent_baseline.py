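"""Conditional law of the true baseline at treatment initiation.

The latent baseline is the error-free value of the biomarker at treatment
initiation:

    u = X_trt beta + Z_trt b + W_trt,     X_trt = Z_trt = (1, t_trt),

which is jointly multivariate normal with the pre-treatment data.  The
standard partitioned-MVN (Schur complement) result gives

    u | y_pre ~ N(mu', v'),
    mu' = X_trt beta + v21 V_pre^{-1} (y_pre - X beta),
    v'  = v22 - v21 V_pre^{-1} v12,

with v12 = Z Psi z_trt' + Cov[W_pre, W_trt] and
v22 = z_trt Psi z_trt' + Var[W_trt].  Note u carries no measurement-error
term, so conditioning can shrink v' below sigma^2.  With no pre-treatment
data the law is the unconditional N(X_trt beta, v22).

The truncation ``u+ = max(0, u)`` is applied only inside the post-treatment
mean and link functions: the latent u keeps its normal law on all of R and
the integrand uses u+, so all probability mass below zero acts as a
baseline of exactly zero without changing the integration variable (the
integrand then has a single kink at u = 0).

In the heavy-tailed model the pre-phase gamma scaling w1 divides the
process contributions to v12 and v22 as well as V_pre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import fbm_cross_cov
from .params import PreParams, SharedParams
from .pre_model import pre_design, pre_marginal_cov

__all__ = ["BaselineLaw", "baseline_joint_blocks", "baseline_conditional", "truncate_baseline"]


@dataclass(frozen=True)
class BaselineLaw:
    """Normal law of the latent baseline: mean ``mu_prime``, variance ``v_prime``."""

    mu_prime: float
    v_prime: float

    def __post_init__(self) -> None:
        if not self.v_prime > 0:
            raise ValueError("v_prime must be > 0")


def baseline_joint_blocks(
    times: np.ndarray,
    t_trt: float,
    pre: PreParams,
    shared: SharedParams,
    w1: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Blocks (V_pre, v12, v22) of the joint normal of (y_pre, u)."""
    times = np.asarray(times, dtype=float)
    if times.size and t_trt < times.max():
        raise ValueError("t_trt must be at or after the last pre-treatment time")
    if not w1 > 0:
        raise ValueError("w1 must be > 0")
    psi = pre.psi()
    z_trt = np.array([1.0, t_trt])
    _, Z = pre_design(times)
    v_pre = pre_marginal_cov(times, pre, shared, w1)
    v12 = Z @ psi @ z_trt + fbm_cross_cov(times, t_trt, pre.fbm) / w1
    v22 = float(z_trt @ psi @ z_trt + pre.fbm.kappa * t_trt ** (2 * pre.fbm.hurst) / w1)
    return v_pre, v12, v22


def baseline_conditional(
    y_pre: np.ndarray,
    times: np.ndarray,
    t_trt: float,
    pre: PreParams,
    shared: SharedParams,
    w1: float = 1.0,
) -> BaselineLaw:
    """Conditional (or, with no pre data, unconditional) law of u."""
    y_pre = np.asarray(y_pre, dtype=float)
    times = np.asarray(times, dtype=float)
    v_pre, v12, v22 = baseline_joint_blocks(times, t_trt, pre, shared, w1)
    mean_trt = pre.beta0 + pre.beta1 * t_trt
    if y_pre.size == 0:
        return BaselineLaw(mean_trt, max(v22, 1e-12))
    X, _ = pre_design(times)
    resid = y_pre - X @ np.array([pre.beta0, pre.beta1])
    sol = np.linalg.solve(v_pre, np.column_stack([resid, v12]))
    mu = mean_trt + float(v12 @ sol[:, 0])
    v = v22 - float(v12 @ sol[:, 1])
    return BaselineLaw(mu, max(v, 1e-12))


def truncate_baseline(u):
    """``u+ = max(0, u)`` (elementwise)."""
    return np.maximum(0.0, u) if np.ndim(u) else max(0.0, float(u))
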