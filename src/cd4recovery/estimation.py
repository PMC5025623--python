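"""Maximum-likelihood estimation and inference for the combined model.

Parameters are optimised without constraints on transformed scales:
logarithms for variances and fBM scales, a logistic transform for the
Hurst indices (range (0, 1)) and a generalised logistic (scaled tanh) for
correlations (range (-1, 1)); means and link coefficients are untransformed.
The optimiser is quasi-Newton (L-BFGS-B) with central-difference gradients.
Confidence intervals come from the observed information (central-difference
Hessian of the transformed-scale log-likelihood at the MLE); interval
endpoints are mapped back through the inverse transforms, hence asymmetric
on the natural scale for variance and correlation parameters.

Model comparison follows the usual conventions for this model family:
generalised likelihood-ratio tests for nested Gaussian models, and BIC
with the penalty computed from the *total* number of observations
(pre plus post), not the number of subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from .joint_likelihood import (
    CohortMatrix,
    cohort_loglik_gh,
    cohort_loglik_laplace,
    _pre_quantities,
)
from .links import LinkFunction
from .modelspec import ModelSpec, QuadratureConfig
from .params import (
    HeavyTailParams,
    ParameterSet,
    PostParams,
    PreParams,
    SharedParams,
)
from .kernels import FbmParams
from .post_model import asymptote_loading, recovery_mean

__all__ = [
    "FitResult",
    "fit",
    "wald_cis",
    "lrt",
    "bic",
    "subject_posterior_modes",
    "predict_band",
    "param_entries",
    "pack_params",
    "unpack_params",
]

_TRANSFORMS = {
    "identity": (lambda x: x, lambda y: y),
    "log": (np.log, np.exp),
    "logit": (lambda x: np.log(x / (1.0 - x)), lambda y: float(expit(y)) if np.ndim(y) == 0 else expit(y)),
    # generalised logistic onto (-1, 1)
    "corr": (lambda x: np.log((1.0 + x) / (1.0 - x)), lambda y: np.tanh(y / 2.0)),
}


@dataclass(frozen=True)
class ParamEntry:
    """One free parameter: its name, transform, and access paths."""

    name: str
    transform: str
    get: callable
    set: callable

    def to_transformed(self, ps: ParameterSet) -> float:
        return float(_TRANSFORMS[self.transform][0](self.get(ps)))

    def from_transformed(self, ps: ParameterSet, theta: float) -> None:
        self.set(ps, float(_TRANSFORMS[self.transform][1](theta)))


def _fbm_entry(block: str, which: str, attr: str, transform: str) -> ParamEntry:
    def get(ps):
        return getattr(getattr(ps, block).fbm, attr)

    def set_(ps, v):
        fbm = getattr(ps, block).fbm
        kw = {"kappa": fbm.kappa, "hurst": fbm.hurst}
        kw[attr] = v
        getattr(ps, block).fbm = FbmParams(**kw)

    return ParamEntry(which, transform, get, set_)


def _attr_entry(name: str, block: str, attr: str, transform: str) -> ParamEntry:
    def get(ps):
        return getattr(getattr(ps, block), attr)

    def set_(ps, v):
        setattr(getattr(ps, block), attr, v)

    return ParamEntry(name, transform, get, set_)


def _coeff_entry(link_attr: str, stratum: int, idx: int, label: str) -> ParamEntry:
    def get(ps):
        return getattr(ps.post, link_attr).coeffs[stratum][idx]

    def set_(ps, v):
        getattr(ps.post, link_attr).coeffs[stratum][idx] = v

    return ParamEntry(label, "identity", get, set_)


def param_entries(spec: ModelSpec, pre_only: bool = False) -> list[ParamEntry]:
    """Ordered free parameters of a model variant."""
    entries = [
        _attr_entry("beta0", "pre", "beta0", "identity"),
        _attr_entry("beta1", "pre", "beta1", "identity"),
        _attr_entry("u00", "pre", "u00", "log"),
        _attr_entry("rho", "pre", "rho", "corr"),
        _attr_entry("u11", "pre", "u11", "log"),
        _fbm_entry("pre", "kappa_pre", "kappa", "log"),
        _fbm_entry("pre", "h_pre", "hurst", "logit"),
        _attr_entry("sigma2", "shared", "sigma2", "log"),
    ]
    if pre_only:
        return entries
    for link_attr, letter, link_spec in (
        ("phi1", "A", spec.phi1_spec),
        ("phi2", "B", spec.phi2_spec),
    ):
        for s in range(link_spec.n_strata):
            tag = f"{letter}t{s + 1}" if link_spec.n_strata > 1 and s < link_spec.n_strata - 1 else letter
            for j in range(link_spec.n_coeffs(s)):
                entries.append(_coeff_entry(link_attr, s, j, f"{tag}{j + 1}"))
    entries += [
        _attr_entry("P", "post", "p_var", "log"),
        _fbm_entry("post", "kappa_post", "kappa", "log"),
        _fbm_entry("post", "h_post", "hurst", "logit"),
    ]
    if spec.heavy_tails:
        entries += [
            _attr_entry("df_pre", "heavy", "v_pre", "log"),
            _attr_entry("df_post", "heavy", "v_post", "log"),
            _attr_entry("rho_moran", "heavy", "rho_moran", "corr"),
        ]
    return entries


def pack_params(ps: ParameterSet, entries: list[ParamEntry]) -> np.ndarray:
    return np.array([e.to_transformed(ps) for e in entries])


def unpack_params(theta: np.ndarray, template: ParameterSet, entries: list[ParamEntry]) -> ParameterSet:
    ps = template.copy()
    for e, th in zip(entries, theta):
        e.from_transformed(ps, th)
    return ps


@dataclass
class FitResult:
    params_hat: ParameterSet
    spec: ModelSpec
    loglik: float
    n_params: int
    n_obs_total: int
    entries: list = field(repr=False, default=None)
    theta_hat: np.ndarray = field(repr=False, default=None)
    vcov_transformed: np.ndarray = field(repr=False, default=None)
    ci_natural: dict = field(default_factory=dict)
    subject_summaries: dict = field(default_factory=dict, repr=False)
    converged: bool = True
    message: str = ""
    n_evaluations: int = 0
    info_pd: bool = True

    @property
    def bic(self) -> float:
        return bic(self.loglik, self.n_params, self.n_obs_total)

    def estimates(self) -> dict:
        return {e.name: e.get(self.params_hat) for e in self.entries}


def _central_grad(f, x, eps=1e-6):
    g = np.empty_like(x)
    for i in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2.0 * eps)
    return g


def _forward_grad(f, x, f0, eps=1e-6):
    g = np.empty_like(x)
    for i in range(x.size):
        xp = x.copy()
        xp[i] += eps
        g[i] = (f(xp) - f0) / eps
    return g


def _forward_hess(f, x, eps=1e-3):
    """One-sided Hessian: ~(k^2+3k)/2 evaluations, O(eps) bias.

    Cheaper than the central scheme by a factor ~4; adequate when the
    Hessian feeds Wald standard errors rather than an optimiser step.
    """
    k = x.size
    f0 = f(x)
    fi = np.empty(k)
    for i in range(k):
        xp = x.copy()
        xp[i] += eps
        fi[i] = f(xp)
    h = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            xij = x.copy()
            xij[i] += eps
            xij[j] += eps
            h[i, j] = h[j, i] = (f(xij) - fi[i] - fi[j] + f0) / eps**2
    return h


def _central_hess(f, x, eps=1e-4):
    k = x.size
    h = np.empty((k, k))
    f0 = f(x)
    fp = np.empty(k)
    fm = np.empty(k)
    for i in range(k):
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        fp[i], fm[i] = f(xp), f(xm)
        h[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / eps**2
    for i in range(k):
        for j in range(i + 1, k):
            xpp, xpm, xmp, xmm = (x.copy() for _ in range(4))
            xpp[[i, j]] += eps
            xmm[[i, j]] -= eps
            xpm[i] += eps
            xpm[j] -= eps
            xmp[i] -= eps
            xmp[j] += eps
            h[i, j] = h[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4.0 * eps**2)
    return h


def _default_template(spec: ModelSpec) -> ParameterSet:
    ps = ParameterSet(
        pre=PreParams(20.0, -1.0, 10.0, 0.3, -0.5, FbmParams(5.0, 0.3)),
        post=PostParams(
            LinkFunction(spec.phi1_spec),
            LinkFunction(spec.phi2_spec),
            3.0,
            FbmParams(3.0, 0.3),
        ),
        shared=SharedParams(3.5),
    )
    if spec.heavy_tails:
        ps.heavy = HeavyTailParams(5.0, 5.0, 0.3)
    return ps


def _staged_init(cm: CohortMatrix, spec: ModelSpec, quad) -> ParameterSet:
    """Moment-based then pre-only-ML starting values.

    Stage 1 fits the pre-treatment marginal model alone (closed form, fast).
    Stage 2 plugs the implied conditional baselines into a crude regression
    of each subject's last post-treatment value to initialise the links,
    with variance components split from the residual spread.
    """
    ps = _default_template(spec)
    # moment start for the pre block
    mask = cm.pre_mask
    if mask.any():
        t_all = cm.t_pre[mask]
        y_all = cm.y_pre[mask]
        X = np.column_stack([np.ones_like(t_all), t_all])
        beta, *_ = np.linalg.lstsq(X, y_all, rcond=None)
        resid_var = float(np.var(y_all - X @ beta)) or 1.0
        ps.pre.beta0, ps.pre.beta1 = float(beta[0]), float(beta[1])
        ps.pre.u00 = 0.5 * resid_var
        ps.pre.u11 = 0.05 * resid_var
        ps.pre.rho = -0.3
        ps.pre.fbm = FbmParams(max(0.25 * resid_var, 1e-3), 0.3)
        ps.shared.sigma2 = max(0.25 * resid_var, 1e-3)
    entries_pre = param_entries(spec, pre_only=True)

    def negll_pre(theta):
        p = unpack_params(theta, ps, entries_pre)
        lp, _, _ = _pre_quantities(cm, p.pre, p.shared, 1.0)
        val = float(lp.sum())
        return -val if np.isfinite(val) else 1e12

    theta0 = pack_params(ps, entries_pre)
    res = optimize.minimize(
        negll_pre, theta0, jac=lambda th: _central_grad(negll_pre, th),
        method="L-BFGS-B", options={"maxiter": 200},
    )
    ps = unpack_params(res.x, ps, entries_pre)

    # stage 2: crude post-phase start from last observed post values
    _, mu, vp = _pre_quantities(cm, ps.pre, ps.shared, 1.0)
    u_plus = np.maximum(mu, 0.0)
    has_post = cm.n_post_obs > 0
    last_idx = np.maximum(cm.n_post_obs - 1, 0)
    y_last = cm.y_post[np.arange(len(cm)), last_idx]
    for link_attr, link_spec in (("phi1", spec.phi1_spec), ("phi2", spec.phi2_spec)):
        link = getattr(ps.post, link_attr)
        from .links import trt_group

        strata = np.atleast_1d(trt_group(cm.t_trt, link_spec))
        resid_list = []
        for s in range(link_spec.n_strata):
            rows = has_post & (strata == s)
            c = link.coeffs[s]
            if link_attr == "phi2":
                c[0] = 0.0  # half-life about 8 months
                continue
            if rows.sum() >= 3 and c.size >= 2:
                A = np.column_stack([np.ones(rows.sum()), u_plus[rows]])
                sol, *_ = np.linalg.lstsq(A, y_last[rows], rcond=None)
                c[0], c[1] = sol
                resid_list.append(y_last[rows] - A @ sol)
            else:
                c[0] = float(np.mean(y_last[rows])) if rows.any() else 20.0
                resid_list.append(y_last[rows] - c[0])
        if link_attr == "phi1" and resid_list:
            rv = float(np.var(np.concatenate(resid_list))) or 1.0
            ps.post.p_var = max(0.4 * rv, 1e-2)
            ps.post.fbm = FbmParams(max(0.4 * rv, 1e-2), 0.3)
    return ps


def fit(
    data,
    spec: ModelSpec,
    init: ParameterSet | None = None,
    quad: QuadratureConfig | None = None,
    maxiter: int = 500,
    compute_ci: bool = True,
    gtol: float = 1e-4,
    ftol: float = 1e-11,
    gradient: str = "central",
    hessian: str = "central",
) -> FitResult:
    """Maximise the cohort log-likelihood for one model variant.

    Initialisation is staged (pre-model alone, then plug-in post-model
    starts, then the joint surface) unless ``init`` is given.  The fit is
    deterministic given data, spec, init and optimiser tolerances.
    """
    spec.check_supported()
    cm = data if isinstance(data, CohortMatrix) else CohortMatrix(data)
    quad = quad or spec.quadrature
    if init is None:
        init = _staged_init(cm, spec, quad)
    else:
        init = spec.template_params(init)
        if spec.heavy_tails and init.heavy is None:
            init.heavy = HeavyTailParams(5.0, 5.0, 0.3)
    entries = param_entries(spec)
    n_eval = [0]

    # deliberately stateless: warm-starting the latent-mode searches across
    # evaluations makes the objective history-dependent, which wrecks
    # finite-difference gradients and line searches
    def negll(theta):
        n_eval[0] += 1
        try:
            ps = unpack_params(theta, init, entries)
            if spec.heavy_tails:
                val = cohort_loglik_laplace(cm, ps, spec)
            else:
                val = cohort_loglik_gh(cm, ps, spec, quad=quad)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError, OverflowError):
            return 1e12
        return -val if np.isfinite(val) else 1e12

    theta0 = pack_params(init, entries)
    if gradient == "forward":
        jac = lambda th: _forward_grad(negll, th, negll(th))  # noqa: E731
    else:
        jac = lambda th: _central_grad(negll, th)  # noqa: E731
    # generous box bounds on the transformed scale: no statistical
    # restriction (variances span e^-25..e^25), but they keep weakly
    # identified parameters from overflowing the inverse transforms
    bounds = [
        (-1e3, 1e3) if e.transform == "identity" else (-25.0, 25.0) for e in entries
    ]
    res = optimize.minimize(
        negll,
        theta0,
        jac=jac,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol, "maxcor": 25},
    )
    def _accept(r):
        gmax = float(np.max(np.abs(r.jac))) if r.jac is not None else np.inf
        # an abnormal line-search exit with a near-zero gradient is still a
        # usable optimum (finite-difference gradients limit the attainable
        # line-search accuracy)
        return bool(r.success) or r.status == 1 or gmax < 100.0 * gtol

    if not _accept(res):
        # one restart with a coarser gradient step: less cancellation noise
        retry = optimize.minimize(
            negll, res.x,
            jac=lambda th: _central_grad(negll, th, eps=1e-5),
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol, "maxcor": 25},
        )
        if retry.fun <= res.fun:
            res = retry
    theta_hat = res.x
    loglik = -float(res.fun)
    params_hat = unpack_params(theta_hat, init, entries)
    converged = _accept(res)
    vcov = None
    cis = {}
    info_pd = False
    if compute_ci:
        if hessian == "forward":
            hess = _forward_hess(negll, theta_hat)
        else:
            hess = _central_hess(negll, theta_hat)  # negll Hessian = observed info
        evals, evecs = np.linalg.eigh((hess + hess.T) / 2.0)
        info_pd = bool(evals.min() > 0)
        # directions with no curvature (boundary correlations, links in
        # strata whose recovery is too fast to observe) get an eigenvalue
        # floor: the data carry no information there, so the interval is
        # honestly wide instead of degenerate
        evals = np.maximum(evals, 1e-6)
        vcov = (evecs / evals) @ evecs.T
    n_obs = int(cm.n_pre_obs.sum() + cm.n_post_obs.sum())
    result = FitResult(
        params_hat=params_hat,
        spec=spec,
        loglik=loglik,
        n_params=len(entries),
        n_obs_total=n_obs,
        entries=entries,
        theta_hat=theta_hat,
        vcov_transformed=vcov,
        converged=converged,
        message=str(res.message),
        n_evaluations=n_eval[0],
        info_pd=info_pd,
    )
    if compute_ci and vcov is not None:
        # pseudo-inverse-based intervals are still reported when the
        # observed information is numerically indefinite; info_pd records it
        result.ci_natural = wald_cis(result)
    result.subject_summaries = subject_posterior_modes(params_hat, cm, spec, quad)
    return result


def wald_cis(fit_result: FitResult, level: float = 0.95) -> dict:
    """Natural-scale Wald intervals from the transformed-scale information.

    Endpoints are computed on the transformed scale and mapped through the
    inverse transform, so intervals respect range restrictions (variances
    positive, correlations inside (-1, 1)) and are generally asymmetric.
    """
    if fit_result.vcov_transformed is None:
        raise ValueError("fit was run without confidence intervals")
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(np.maximum(np.diag(fit_result.vcov_transformed), 0.0))
    out = {}
    with np.errstate(over="ignore"):  # an unbounded variance CI maps to inf
        for e, th, s in zip(fit_result.entries, fit_result.theta_hat, se):
            inv = _TRANSFORMS[e.transform][1]
            lo, hi = float(inv(th - z * s)), float(inv(th + z * s))
            out[e.name] = (min(lo, hi), float(inv(th)), max(lo, hi))
    return out


def lrt(loglik_reduced: float, loglik_full: float, df: int) -> tuple[float, float]:
    """Generalised likelihood-ratio test of nested models.

    Returns ``(delta2l, p)`` with ``delta2l = 2 (l_full - l_reduced)``
    referred to a chi-squared distribution with ``df`` degrees of freedom.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    delta = 2.0 * (loglik_full - loglik_reduced)
    if delta < -1e-6:
        raise ValueError(
            f"full model has lower log-likelihood than reduced (delta2l={delta:.3g}); "
            "models are not nested or a fit failed"
        )
    delta = max(delta, 0.0)
    return delta, float(stats.chi2.sf(delta, df))


def bic(loglik: float, n_params: int, n_obs_total: int) -> float:
    """``-2 l + k log(n)`` with n the total observation count (pre + post)."""
    if n_obs_total < 1:
        raise ValueError("n_obs_total must be >= 1")
    return -2.0 * loglik + n_params * np.log(n_obs_total)


def subject_posterior_modes(
    params: ParameterSet,
    data,
    spec: ModelSpec,
    quad: QuadratureConfig | None = None,
) -> dict:
    """Per-subject posterior modes of the latent variables at fixed parameters.

    For Gaussian models: the mode and curvature-based sd of
    f(u | y_pre, y_post).  For heavy-tailed models additionally the modes
    of the gamma scaling variables w1, w2 (from the Laplace inner optimum).
    """
    cm = data if isinstance(data, CohortMatrix) else CohortMatrix(data)
    if spec.heavy_tails:
        _, terms = cohort_loglik_laplace(cm, params, spec, return_subject_terms=True)
    else:
        _, terms = cohort_loglik_gh(cm, params, spec, quad=quad, return_subject_terms=True)
    terms = dict(terms)
    terms["subject_id"] = list(cm.ids)
    return terms


def predict_band(
    params: ParameterSet,
    u_true: float,
    t_trt: float,
    t_grid: np.ndarray,
    coverage: float = 0.90,
    include_measurement_error: bool = True,
) -> dict:
    """Pointwise prediction band on the original (back-transformed) scale.

    For a hypothetical subject with known true baseline ``u_true`` the
    response on the analysis scale at time t is normal with mean
    ``g(t, u+)`` and variance ``P c(t)^2 + kappa_post t^{2H} + sigma^2``;
    the band is formed from normal quantiles there, then squared (the
    analysis scale is the square root of the raw measurement) and clipped
    at zero.
    """
    if u_true < 0:
        raise ValueError("u_true must be >= 0")
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid < 0):
        raise ValueError("t_grid must be >= 0")
    u_plus = float(u_true)
    phi1 = float(params.post.phi1(u_plus, t_trt))
    phi2 = float(params.post.phi2(u_plus, t_trt))
    mean = np.asarray(recovery_mean(t_grid, u_plus, phi1, phi2))
    c = np.asarray(asymptote_loading(t_grid, phi2))
    var = params.post.p_var * c**2 + params.post.fbm.kappa * np.where(
        t_grid > 0, t_grid, 1.0
    ) ** (2 * params.post.fbm.hurst) * (t_grid > 0)
    if include_measurement_error:
        var = var + params.shared.sigma2
    z = stats.norm.ppf(0.5 + coverage / 2.0)
    lo = np.maximum(mean - z * np.sqrt(var), 0.0)
    hi = np.maximum(mean + z * np.sqrt(var), 0.0)
    return {
        "t": t_grid,
        "mean": mean**2,
        "lower": lo**2,
        "upper": hi**2,
        "mean_sqrt_scale": mean,
    }


# ---------------------------------------------------------------------------
# FitResult (de)serialisation: everything needed to reload and re-evaluate
# ---------------------------------------------------------------------------

def _spec_to_dict(spec: ModelSpec) -> dict:
    def link_dict(ls):
        return {
            "form": list(ls.form) if isinstance(ls.form, tuple) else ls.form,
            "knots": list(ls.knots),
            "stratified": ls.stratified,
            "stratum_bounds": list(ls.stratum_bounds),
        }

    return {
        "name": spec.name,
        "phi1": link_dict(spec.phi1_spec),
        "phi2": link_dict(spec.phi2_spec),
        "heavy_tails": spec.heavy_tails,
        "n_quad": spec.quadrature.n_points,
        "recenter": spec.quadrature.recenter,
    }


def _spec_from_dict(d: dict) -> ModelSpec:
    from .links import LinkSpec

    def link_spec(ld):
        form = tuple(ld["form"]) if isinstance(ld["form"], list) else ld["form"]
        return LinkSpec(
            form=form,
            knots=tuple(ld["knots"]),
            stratified=ld["stratified"],
            stratum_bounds=tuple(ld["stratum_bounds"]),
        )

    return ModelSpec(
        phi1_spec=link_spec(d["phi1"]),
        phi2_spec=link_spec(d["phi2"]),
        heavy_tails=d["heavy_tails"],
        quadrature=QuadratureConfig(d["n_quad"], d["recenter"]),
        name=d.get("name", ""),
    )


def save_fit(fit_result: FitResult, path) -> None:
    payload = {
        "spec": _spec_to_dict(fit_result.spec),
        "theta_transformed": list(map(float, fit_result.theta_hat)),
        "estimates": {k: float(v) for k, v in fit_result.estimates().items()},
        "loglik": fit_result.loglik,
        "n_params": fit_result.n_params,
        "n_obs_total": fit_result.n_obs_total,
        "bic": fit_result.bic,
        "vcov_transformed": None
        if fit_result.vcov_transformed is None
        else [list(map(float, row)) for row in fit_result.vcov_transformed],
        "ci_natural": {k: list(v) for k, v in fit_result.ci_natural.items()},
        "converged": fit_result.converged,
        "message": fit_result.message,
        "subject_summaries": {
            k: (list(map(float, v)) if not isinstance(v, list) else v)
            for k, v in fit_result.subject_summaries.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_fit(path) -> FitResult:
    with open(path) as fh:
        payload = json.load(fh)
    spec = _spec_from_dict(payload["spec"])
    entries = param_entries(spec)
    template = _default_template(spec)
    theta = np.array(payload["theta_transformed"])
    params = unpack_params(theta, template, entries)
    return FitResult(
        params_hat=params,
        spec=spec,
        loglik=payload["loglik"],
        n_params=payload["n_params"],
        n_obs_total=payload["n_obs_total"],
        entries=entries,
        theta_hat=theta,
        vcov_transformed=None
        if payload["vcov_transformed"] is None
        else np.array(payload["vcov_transformed"]),
        ci_natural={k: tuple(v) for k, v in payload["ci_natural"].items()},
        subject_summaries=payload.get("subject_summaries", {}),
        converged=payload["converged"],
        message=payload["message"],
    )
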