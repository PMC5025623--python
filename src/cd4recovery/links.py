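"""Link functions mapping the true baseline to post-treatment curve parameters.

The asymptotic recovery curve for each subject is governed by two scalars:
phi1 (long-term maximum on the analysis scale) and phi2 (log recovery rate).
Each is modelled as a deterministic function of the truncated true baseline
``u+ = max(0, u)``, chosen from

* ``constant`` -- one coefficient, no dependence on u+;
* ``linear``   -- intercept + slope * u+;
* ``ncs``      -- a natural cubic spline in u+ on a truncated-power basis
  (Hastie/Tibshirani/Friedman construction), linear beyond the boundary
  knots.  Default knots 15.5, 17.5, 19.5, 22 on the square-root CD4 scale.

Optionally the link is stratified by the time from seroconversion to
treatment initiation, with cutpoints at 0.5 and 1 year and closed upper
endpoints (a subject treated at exactly 0.5 y belongs to the early group).
Strata may use different forms (e.g. linear for early treatment, spline for
late treatment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_KNOTS",
    "DEFAULT_STRATUM_BOUNDS",
    "LinkSpec",
    "LinkFunction",
    "trt_group",
    "ncs_basis",
    "link_value",
]

DEFAULT_KNOTS = (15.5, 17.5, 19.5, 22.0)
DEFAULT_STRATUM_BOUNDS = (0.5, 1.0)

_FORMS = ("constant", "linear", "ncs")


@dataclass(frozen=True)
class LinkSpec:
    """Declarative description of one link function.

    ``form`` is a single form applied to all strata, or a tuple giving a
    form per stratum (length ``len(stratum_bounds) + 1``) when
    ``stratified`` is true.
    """

    form: str | tuple[str, ...] = "constant"
    knots: tuple[float, ...] = DEFAULT_KNOTS
    stratified: bool = False
    stratum_bounds: tuple[float, ...] = DEFAULT_STRATUM_BOUNDS

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        if knots.size >= 2 and np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        forms = self.form if isinstance(self.form, tuple) else (self.form,)
        for f in forms:
            if f not in _FORMS:
                raise ValueError(f"unknown link form {f!r}; expected one of {_FORMS}")
            if f == "ncs" and knots.size < 2:
                raise ValueError("ncs link requires at least 2 knots")
        bounds = np.asarray(self.stratum_bounds, dtype=float)
        if np.any(bounds <= 0) or np.any(np.diff(bounds) <= 0):
            raise ValueError("stratum_bounds must be positive and strictly increasing")
        if isinstance(self.form, tuple):
            if not self.stratified:
                raise ValueError("per-stratum forms require stratified=True")
            if len(self.form) != self.n_strata:
                raise ValueError(
                    f"expected {self.n_strata} per-stratum forms, got {len(self.form)}"
                )

    @property
    def n_strata(self) -> int:
        return len(self.stratum_bounds) + 1 if self.stratified else 1

    def form_for(self, stratum: int) -> str:
        if isinstance(self.form, tuple):
            return self.form[stratum]
        return self.form

    def n_coeffs(self, stratum: int) -> int:
        form = self.form_for(stratum)
        if form == "constant":
            return 1
        if form == "linear":
            return 2
        return len(self.knots)

    @property
    def total_coeffs(self) -> int:
        return sum(self.n_coeffs(s) for s in range(self.n_strata))


def trt_group(t_trt, spec: LinkSpec):
    """Stratum index for a treatment-initiation time (years).

    Index 0 for ``t_trt <= bounds[0]``, 1 for ``(bounds[0], bounds[1]]``,
    and so on; boundary values belong to the earlier group.  Always 0 for a
    non-stratified link.
    """
    t = np.asarray(t_trt, dtype=float)
    if np.any(t < 0):
        raise ValueError("time to treatment must be non-negative")
    if not spec.stratified:
        out = np.zeros(t.shape, dtype=np.intp)
    else:
        out = np.searchsorted(np.asarray(spec.stratum_bounds), t, side="left")
    return out if out.ndim else int(out)


def ncs_basis(x, knots) -> np.ndarray:
    """Natural cubic spline basis (truncated power construction).

    With K strictly increasing knots xi_1 < ... < xi_K the basis is
    N1(x) = 1, N2(x) = x, and for k = 1..K-2

        N_{k+2}(x) = d_k(x) - d_{K-1}(x),
        d_k(x) = [ (x - xi_k)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_k),

    which is linear outside [xi_1, xi_K].  ``x`` may be any array shape;
    output gains a trailing axis of length K.
    """
    knots = np.asarray(knots, dtype=float)
    if knots.size < 2 or np.any(np.diff(knots) <= 0):
        raise ValueError("need at least 2 strictly increasing knots")
    x = np.asarray(x, dtype=float)
    k_last = knots[-1]
    cube_last = np.maximum(x - k_last, 0.0) ** 3

    def d(k_idx: int) -> np.ndarray:
        xk = knots[k_idx]
        return (np.maximum(x - xk, 0.0) ** 3 - cube_last) / (k_last - xk)

    cols = [np.ones_like(x), x]
    if knots.size > 2:
        d_pen = d(knots.size - 2)
        cols.extend(d(k) - d_pen for k in range(knots.size - 2))
    return np.stack(cols, axis=-1)


def _eval_form(form: str, coeffs: np.ndarray, u_plus: np.ndarray, knots) -> np.ndarray:
    coeffs = np.asarray(coeffs, dtype=float)
    if form == "constant":
        if coeffs.shape != (1,):
            raise ValueError("constant link takes exactly 1 coefficient")
        return np.full_like(np.asarray(u_plus, dtype=float), coeffs[0])
    if form == "linear":
        if coeffs.shape != (2,):
            raise ValueError("linear link takes exactly 2 coefficients")
        return coeffs[0] + coeffs[1] * np.asarray(u_plus, dtype=float)
    basis = ncs_basis(u_plus, knots)
    if coeffs.shape != (basis.shape[-1],):
        raise ValueError(
            f"ncs link with {basis.shape[-1]} knots takes {basis.shape[-1]} coefficients"
        )
    return basis @ coeffs


def link_value(u_plus, t_trt, spec: LinkSpec, coeffs, covariate_offset=0.0) -> np.ndarray | float:
    """Evaluate the link at ``u_plus`` for a subject treated at ``t_trt``.

    ``coeffs`` is a sequence with one coefficient vector per stratum.
    ``u_plus`` may be an array (values for one subject); ``t_trt`` is a
    scalar selecting that subject's stratum.  ``covariate_offset`` is an
    optional additive linear-predictor term (x' beta for subject-level
    covariates such as age or regimen); it is a structural hook only --
    no fitted defaults ship with the package.
    """
    u_plus = np.asarray(u_plus, dtype=float)
    if np.any(u_plus < 0):
        raise ValueError("u_plus must be non-negative")
    g = trt_group(float(t_trt), spec)
    out = _eval_form(spec.form_for(g), coeffs[g], u_plus, spec.knots) + covariate_offset
    return out if out.ndim else float(out)


@dataclass
class LinkFunction:
    """A link specification bundled with its fitted/true coefficients."""

    spec: LinkSpec
    coeffs: tuple[np.ndarray, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.coeffs is None:
            self.coeffs = tuple(
                np.zeros(self.spec.n_coeffs(s)) for s in range(self.spec.n_strata)
            )
        else:
            self.coeffs = tuple(np.asarray(c, dtype=float) for c in self.coeffs)
            for s, c in enumerate(self.coeffs):
                if c.shape != (self.spec.n_coeffs(s),):
                    raise ValueError(
                        f"stratum {s}: expected {self.spec.n_coeffs(s)} coefficients, "
                        f"got {c.shape}"
                    )

    def __call__(self, u_plus, t_trt, covariate_offset=0.0):
        return link_value(u_plus, t_trt, self.spec, self.coeffs, covariate_offset)

    def copy(self) -> "LinkFunction":
        return LinkFunction(self.spec, tuple(c.copy() for c in self.coeffs))
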