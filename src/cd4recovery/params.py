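"""Natural-scale parameter containers for the combined pre/post model.

The full parameter set splits into four blocks:

* ``pre``    -- linear mixed model for the pre-treatment decline: population
  intercept/slope (beta0, beta1), random intercept/slope covariance
  (U00, U11, rho) and the pre-phase fBM (kappa_pre, H_pre);
* ``post``   -- the recovery model: phi1/phi2 link functions of the
  truncated baseline, the random-asymptote variance P and the post-phase
  fBM (kappa_post, H_post);
* ``shared`` -- the measurement-error variance sigma^2, shared by the two
  phases;
* ``heavy``  -- optional heavy-tail block: gamma-scaling degrees of freedom
  (v_pre, v_post) and the Moran-copula correlation rho_moran.

These are plain natural-scale values; the optimisation transforms
(log / logistic / generalised logistic) live in :mod:`cd4recovery.estimation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import FbmParams
from .links import LinkFunction

__all__ = ["PreParams", "SharedParams", "PostParams", "HeavyTailParams", "ParameterSet"]


@dataclass
class PreParams:
    beta0: float
    beta1: float
    u00: float
    u11: float
    rho: float
    fbm: FbmParams

    def __post_init__(self) -> None:
        if self.u00 < 0 or self.u11 < 0:
            raise ValueError("random-effect variances must be >= 0")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1")

    def psi(self) -> np.ndarray:
        """Random intercept/slope covariance matrix (2x2, PSD)."""
        cov = self.rho * np.sqrt(self.u00 * self.u11)
        return np.array([[self.u00, cov], [cov, self.u11]])


@dataclass
class SharedParams:
    sigma2: float

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be > 0")


@dataclass
class PostParams:
    phi1: LinkFunction
    phi2: LinkFunction
    p_var: float
    fbm: FbmParams

    def __post_init__(self) -> None:
        if self.p_var < 0:
            raise ValueError("random-asymptote variance P must be >= 0")


@dataclass
class HeavyTailParams:
    v_pre: float
    v_post: float
    rho_moran: float

    def __post_init__(self) -> None:
        if not (self.v_pre > 0 and self.v_post > 0):
            raise ValueError("degrees of freedom must be > 0")
        if not abs(self.rho_moran) < 1:
            raise ValueError("|rho_moran| must be < 1")


@dataclass
class ParameterSet:
    pre: PreParams
    post: PostParams
    shared: SharedParams
    heavy: HeavyTailParams | None = field(default=None)

    def copy(self) -> "ParameterSet":
        # hand-rolled deep copy: called once per likelihood evaluation
        # inside optimisation loops, where copy.deepcopy is too slow
        pre = PreParams(self.pre.beta0, self.pre.beta1, self.pre.u00,
                        self.pre.u11, self.pre.rho, self.pre.fbm)
        post = PostParams(self.post.phi1.copy(), self.post.phi2.copy(),
                          self.post.p_var, self.post.fbm)
        shared = SharedParams(self.shared.sigma2)
        heavy = None
        if self.heavy is not None:
            heavy = HeavyTailParams(self.heavy.v_pre, self.heavy.v_post,
                                    self.heavy.rho_moran)
        return ParameterSet(pre, post, shared, heavy)
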