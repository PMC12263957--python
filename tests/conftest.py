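import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from pvrnn_mw import core


@pytest.fixture
def tiny_specs():
    return [core.LayerSpec(4, 2, 2.0, 0.5), core.LayerSpec(3, 1, 3.0, 0.2)]


@pytest.fixture
def tiny_params(tiny_specs):
    """Small two-layer network with randomized biases so that nothing is
    degenerate."""
    p = core.init_params(tiny_specs, rx=2, seed=1)
    rng = np.random.default_rng(5)
    for name in ("bh", "bmup", "bsigp", "bmuq", "bsigq", "bout"):
        arr = getattr(p, name)
        arr += 0.1 * rng.standard_normal(arr.shape)
    return p


def zero_params(specs, rx=2):
    """All-zero weights/biases (deterministic dynamics for hand checks)."""
    p = core.init_params(specs, rx=rx, seed=0)
    for name, arr in p.trainable().items():
        arr[:] = 0.0
    return p


@pytest.fixture
def random_posterior_problem(tiny_params, tiny_specs):
    """A fixed small inference problem: adaptive variables, noise draws
    and targets for a 7-step, 3-sequence batch."""
    rng = np.random.default_rng(7)
    T, B, L = 7, 3, 2
    nzm = tiny_params.Wzd.shape[2]
    Amu = 0.3 * rng.standard_normal((T, L, nzm, B))
    Asig = 0.3 * rng.standard_normal((T, L, nzm, B))
    for l, s in enumerate(tiny_specs):
        Amu[:, l, s.n_z:, :] = 0.0
        Asig[:, l, s.n_z:, :] = 0.0
    eps = rng.standard_normal((T, L, nzm, B))
    targets = rng.uniform(-0.8, 0.8, size=(T, 2, B))
    return Amu, Asig, eps, targets
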