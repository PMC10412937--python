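import numpy as np
import pytest

from laminarfp.synth import default_scene, simulate_scene


@pytest.fixture(scope="session")
def default_bilateral():
    """One 60 s default-scene realization, shared across tests."""
    rec, gt = simulate_scene(default_scene(), duration=60.0, fs=1000.0, seed=123)
    return rec, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
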