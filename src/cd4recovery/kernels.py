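"""Fractional Brownian motion covariance algebra.

Both the pre- and post-treatment stochastic components of the trajectory
model are scaled fractional Brownian motion (fBM): a zero-mean Gaussian
process ``W`` with ``W_0 = 0``, ``Var[W_t] = kappa * |t|**(2H)`` and

    Cov[W_s, W_t] = kappa/2 * (|s|**(2H) + |t|**(2H) - |t - s|**(2H)),

where ``kappa > 0`` is the variance of the process at t = 1 and the Hurst
index ``H`` lies in (0, 1).  ``H = 1/2`` recovers standard Brownian motion
(``Cov = kappa * min(s, t)``); ``H < 1/2`` gives negatively correlated
increments and mean-reverting, jagged sample paths, which is the regime
repeatedly estimated for CD4 counts.

This module only does covariance algebra on finite grids of observation
times; path simulation lives in :mod:`cd4recovery.synthetic` and uses the
Cholesky factor of these matrices (exact for the finite-dimensional
distributions required).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FbmParams", "fbm_cov", "fbm_cov_matrix", "fbm_cross_cov", "chol_psd"]


@dataclass(frozen=True)
class FbmParams:
    """Scale and Hurst index of a fractional Brownian motion process.

    Parameters
    ----------
    kappa
        Positive scale: the variance of the process at t = 1, in squared
        response units.
    hurst
        Hurst index, strictly inside (0, 1).
    """

    kappa: float
    hurst: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.kappa) and self.kappa > 0):
            raise ValueError(f"kappa must be finite and > 0, got {self.kappa}")
        if not (np.isfinite(self.hurst) and 0.0 < self.hurst < 1.0):
            raise ValueError(f"hurst must lie in (0, 1), got {self.hurst}")


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(times)):
        raise ValueError("observation times must be finite")
    if np.any(times < 0):
        raise ValueError("observation times must be non-negative")
    return times


def _abs_pow(x: np.ndarray, two_h: float) -> np.ndarray:
    # |x|**(2H) with the convention 0**(2H) == 0 exactly, even for
    # pathological floating-point H where 0**x could misbehave.
    ax = np.abs(x)
    out = np.zeros_like(ax)
    nz = ax > 0
    out[nz] = ax[nz] ** two_h
    return out


def fbm_cov(s: float, t: float, params: FbmParams) -> float:
    """Covariance of the fBM at two non-negative times.

    Returns ``kappa/2 * (|s|^2H + |t|^2H - |t-s|^2H)``; symmetric in
    ``(s, t)`` with ``fbm_cov(t, t) = kappa * |t|^2H``.
    """
    st = _check_times(np.array([s, t]))
    two_h = 2.0 * params.hurst
    parts = _abs_pow(np.array([st[0], st[1], st[1] - st[0]]), two_h)
    return 0.5 * params.kappa * (parts[0] + parts[1] - parts[2])


def fbm_cov_matrix(times: np.ndarray, params: FbmParams) -> np.ndarray:
    """Covariance matrix of the fBM on a grid of times.

    ``times`` may have an arbitrary leading batch shape ``(..., n)``; the
    result has shape ``(..., n, n)``.  Times need not be sorted or distinct
    (duplicates yield a singular matrix, made harmless downstream by the
    measurement-error nugget).
    """
    times = _check_times(times)
    two_h = 2.0 * params.hurst
    pw = _abs_pow(times, two_h)
    diff = _abs_pow(times[..., :, None] - times[..., None, :], two_h)
    return 0.5 * params.kappa * (pw[..., :, None] + pw[..., None, :] - diff)


def fbm_cross_cov(times: np.ndarray, t_star: float | np.ndarray, params: FbmParams) -> np.ndarray:
    """Vector ``Cov[W_times, W_{t_star}]`` (batched over leading dims)."""
    times = _check_times(times)
    t_star = _check_times(np.asarray(t_star, dtype=float))[..., None]
    two_h = 2.0 * params.hurst
    pw = _abs_pow(times, two_h)
    ps = _abs_pow(t_star, two_h)
    diff = _abs_pow(times - t_star, two_h)
    return 0.5 * params.kappa * (pw + ps - diff)


def chol_psd(mat: np.ndarray, max_jitter: float = 1e-8) -> np.ndarray:
    """Cholesky factor with escalating diagonal jitter (1e-12 -> 1e-8).

    Near-duplicate visit times occur in realistic data, producing matrices
    that are PSD only up to rounding; a tiny diagonal ridge restores
    positive definiteness.  Raises ``numpy.linalg.LinAlgError`` if even the
    largest jitter fails.
    """
    mat = np.asarray(mat, dtype=float)
    jitter = 0.0
    while True:
        try:
            bump = jitter * np.eye(mat.shape[-1])
            return np.linalg.cholesky(mat + bump)
        except np.linalg.LinAlgError:
            if jitter >= max_jitter:
                raise
            jitter = 1e-12 if jitter == 0.0 else jitter * 100.0
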