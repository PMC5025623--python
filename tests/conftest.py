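import numpy as np
import pytest

from cd4recovery import (
    FbmParams,
    HeavyTailParams,
    LinkFunction,
    ParameterSet,
    PostParams,
    PreParams,
    SharedParams,
    SubjectRecord,
)
from cd4recovery.modelspec import preset


@pytest.fixture
def rng():
    return np.random.default_rng(20160915)


@pytest.fixture
def model2_params():
    """Linear-link Gaussian parameter set of realistic magnitude."""
    spec = preset("model2")
    return ParameterSet(
        pre=PreParams(22.4, -1.4, 13.0, 0.25, -0.6, FbmParams(5.9, 0.30)),
        post=PostParams(
            LinkFunction(spec.phi1_spec, (np.array([11.4, 0.69]),)),
            LinkFunction(spec.phi2_spec, (np.array([-3.3, 0.24]),)),
            3.0,
            FbmParams(3.1, 0.40),
        ),
        shared=SharedParams(1.95**2),
    )


@pytest.fixture
def model1_params():
    spec = preset("model1")
    return ParameterSet(
        pre=PreParams(22.4, -1.4, 12.4, 0.55, -0.65, FbmParams(9.7, 0.11)),
        post=PostParams(
            LinkFunction(spec.phi1_spec, (np.array([25.9]),)),
            LinkFunction(spec.phi2_spec, (np.array([-0.16]),)),
            11.1,
            FbmParams(7.6, 0.08),
        ),
        shared=SharedParams(1.25**2),
    )


def random_subject(rng, params, n_pre=None, n_post=None, sid="s0"):
    """A random small subject with data of plausible magnitude.

    Values are drawn around the model mean but not from the model itself;
    likelihood tests only need a valid point at which to evaluate.
    """
    n = rng.integers(1, 5) if n_pre is None else n_pre
    m = rng.integers(1, 5) if n_post is None else n_post
    t_trt = float(rng.uniform(0.3, 3.0))
    t_pre = np.sort(rng.uniform(0.0, t_trt * 0.999, n))
    t_post = np.sort(rng.uniform(0.05, 4.0, m))
    y_pre = params.pre.beta0 + params.pre.beta1 * t_pre + rng.normal(0, 3, n)
    y_post = 18.0 + rng.normal(0, 3, m)
    return SubjectRecord(sid, t_pre, y_pre, t_post, y_post, t_trt)
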