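"""Pre-treatment linear mixed model with fBM and measurement error.

For subject i with pre-treatment times t and values y,

    y = X beta + Z b + W_pre + e,
    b ~ MVN(0, Psi),   W_pre ~ fBM(kappa_pre, H_pre),   e ~ MVN(0, sigma^2 I),

with X = Z = (1, t) (random intercepts and slopes).  Marginally

    y ~ MVN(X beta, V_pre),   V_pre = Z Psi Z' + Sigma_pre + sigma^2 I,

so the pre-phase log-likelihood is a closed-form MVN density.  In the
heavy-tailed variant the process block is scaled by a latent gamma
variable: ``Sigma_pre / w1`` (``w1 = 1`` recovers the Gaussian model).

Random effects and process values are never instantiated here (they are
marginalised analytically); the simulator draws them explicitly.
"""

from __future__ import annotations

import numpy as np

from .kernels import chol_psd, fbm_cov_matrix
from .params import PreParams, SharedParams

__all__ = ["pre_design", "pre_marginal_cov", "pre_loglik", "mvn_loglik"]

_LOG_2PI = np.log(2.0 * np.pi)


def pre_design(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fixed- and random-effects design matrices (identical: columns 1, t)."""
    times = np.asarray(times, dtype=float)
    X = np.column_stack([np.ones_like(times), times])
    return X, X


def pre_marginal_cov(
    times: np.ndarray,
    pre: PreParams,
    shared: SharedParams,
    w1: float = 1.0,
) -> np.ndarray:
    """Marginal covariance ``Z Psi Z' + Sigma_pre / w1 + sigma^2 I``."""
    if not w1 > 0:
        raise ValueError("w1 must be > 0")
    times = np.asarray(times, dtype=float)
    _, Z = pre_design(times)
    V = Z @ pre.psi() @ Z.T + fbm_cov_matrix(times, pre.fbm) / w1
    V[np.diag_indices_from(V)] += shared.sigma2
    return V


def mvn_loglik(y: np.ndarray, mean: np.ndarray, cov: np.ndarray, context: str = "") -> float:
    """Dense MVN log-density via a jittered Cholesky factor."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        return 0.0
    try:
        L = chol_psd(cov)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular covariance{' for ' + context if context else ''}"
        ) from err
    z = np.linalg.solve(L, y - mean)
    return float(-0.5 * (y.size * _LOG_2PI) - np.log(np.diag(L)).sum() - 0.5 * z @ z)


def pre_loglik(
    y_pre: np.ndarray,
    times: np.ndarray,
    pre: PreParams,
    shared: SharedParams,
    w1: float = 1.0,
    subject_id: str = "",
) -> float:
    """Marginal MVN log-density of the pre-treatment series.

    An empty series contributes exactly 0 (the log of an empty product);
    subjects with no pre-treatment data enter the joint likelihood through
    the unconditional baseline law instead.
    """
    y_pre = np.asarray(y_pre, dtype=float)
    times = np.asarray(times, dtype=float)
    if y_pre.size != times.size:
        raise ValueError("y_pre and times must have equal length")
    if y_pre.size == 0:
        return 0.0
    X, _ = pre_design(times)
    mean = X @ np.array([pre.beta0, pre.beta1])
    return mvn_loglik(y_pre, mean, pre_marginal_cov(times, pre, shared, w1), context=subject_id)
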