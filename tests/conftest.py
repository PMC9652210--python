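"""Shared fixtures: phantoms are generated once per session."""

import numpy as np
import pytest

from acetaver.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Default zero-noise phantom: true AV 16.1°, inclination 45°, left."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def noisy_phantom():
    """Phantom with 0.3 mm Gaussian vertex noise (seed 0)."""
    return make_phantom(PhantomSpec(vertex_noise_sd_mm=0.3, rng_seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
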