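import numpy as np
import pytest

from nodulecad.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """A 64^3 phantom with mid-sized nodules (fast)."""
    spec = PhantomSpec(volume_shape=(64, 64, 64), n_nodules=4,
                       diameter_range=(6.0, 14.0), n_vessels=4, seed=7)
    return (spec,) + generate_phantom(spec)


@pytest.fixture(scope="session")
def default_phantom():
    """The default 128^3 phantom (used where mask geometry matters)."""
    spec = PhantomSpec(seed=3)
    return (spec,) + generate_phantom(spec)
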