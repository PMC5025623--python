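"""Declarative model variants and the standard six-model ladder.

A :class:`ModelSpec` fixes everything about a model other than its
parameter values: the phi1/phi2 link forms (with optional stratification
by treatment timing), whether the heavy-tailed Moran-copula extension is
on, and the quadrature settings.  The named presets reproduce the usual
ladder of variants fitted in this framework:

====== ================================================== ===========
preset links (phi1 / phi2)                                 heavy tails
====== ================================================== ===========
model1 constant / constant                                 no
model2 linear / linear                                     no
model3 NCS / NCS                                           no
model4 linear / linear, stratified by treatment timing     no
model5 linear (early strata) + NCS (late), stratified      no
model6 as model4                                           yes
====== ================================================== ===========

Two documented non-convergent extensions (a random effect on phi2, and an
independent effect of the pre-treatment slope) are exposed as flags that
raise at fit time rather than silently fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .links import LinkFunction, LinkSpec
from .params import ParameterSet

__all__ = ["ModelSpec", "QuadratureConfig", "UnsupportedModelError", "preset", "PRESETS"]


class UnsupportedModelError(NotImplementedError):
    """Raised for model extensions that are specified but known not to converge."""


@dataclass(frozen=True)
class QuadratureConfig:
    """Gauss-Hermite settings for the one-latent (Gaussian) models."""

    n_points: int = 15
    recenter: bool = True

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")


@dataclass(frozen=True)
class ModelSpec:
    phi1_spec: LinkSpec = field(default_factory=LinkSpec)
    phi2_spec: LinkSpec = field(default_factory=LinkSpec)
    heavy_tails: bool = False
    quadrature: QuadratureConfig = field(default_factory=QuadratureConfig)
    random_phi2: bool = False
    pre_slope_effect: bool = False
    name: str = ""

    def check_supported(self) -> None:
        if self.random_phi2:
            raise UnsupportedModelError(
                "a subject-specific random effect on phi2 is not supported "
                "(reported as non-convergent in this model family)"
            )
        if self.pre_slope_effect:
            raise UnsupportedModelError(
                "an independent effect of the pre-treatment slope is not supported "
                "(reported as non-convergent in this model family)"
            )

    def n_params(self) -> int:
        n = 8  # beta0, beta1, U00, rho, U11, kappa_pre, H_pre, sigma2
        n += self.phi1_spec.total_coeffs + self.phi2_spec.total_coeffs
        n += 3  # P, kappa_post, H_post
        if self.heavy_tails:
            n += 3  # v_pre, v_post, rho_moran
        return n

    def template_params(self, base: ParameterSet) -> ParameterSet:
        """A copy of ``base`` with link functions rebuilt to match this spec.

        Coefficients are embedded where the nesting allows it exactly: a
        constant link becomes (c, 0, ...), a linear link occupies the first
        two columns of the NCS basis (which reproduce 1 and x), and an
        unstratified link is replicated across strata.  This makes a
        reduced-model fit a valid starting point for its extensions.
        """
        out = base.copy()
        for attr, spec in (("phi1", self.phi1_spec), ("phi2", self.phi2_spec)):
            old = getattr(out.post, attr)
            if old.spec == spec:
                continue
            new = LinkFunction(spec)
            for s in range(spec.n_strata):
                src = old.coeffs[min(s, len(old.coeffs) - 1)]
                dst = new.coeffs[s]
                n_copy = min(src.size, dst.size)
                dst[:n_copy] = src[:n_copy]
            setattr(out.post, attr, new)
        return out


def _strat(form, stratified=False) -> LinkSpec:
    return LinkSpec(form=form, stratified=stratified)


PRESETS: dict[str, ModelSpec] = {
    "model1": ModelSpec(_strat("constant"), _strat("constant"), name="model1"),
    "model2": ModelSpec(_strat("linear"), _strat("linear"), name="model2"),
    "model3": ModelSpec(_strat("ncs"), _strat("ncs"), name="model3"),
    "model4": ModelSpec(
        _strat("linear", True), _strat("linear", True), name="model4"
    ),
    "model5": ModelSpec(
        _strat(("linear", "linear", "ncs"), True),
        _strat(("linear", "linear", "ncs"), True),
        name="model5",
    ),
    "model6": ModelSpec(
        _strat("linear", True), _strat("linear", True), heavy_tails=True, name="model6"
    ),
}


def preset(name: str, **overrides) -> ModelSpec:
    """Fetch a named preset, optionally overriding fields (e.g. quadrature)."""
    try:
        spec = PRESETS[name]
    except KeyError as err:
        raise KeyError(f"unknown model preset {name!r}; choose from {sorted(PRESETS)}") from err
    return replace(spec, **overrides) if overrides else spec
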