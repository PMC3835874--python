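import numpy as np
import pytest

from blocknlm import NoiseParams, Volume, add_speckle, default_phantom_spec, make_phantom

try:
    from hypothesis import settings

    settings.register_profile("suite", deadline=None, derandomize=True)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(1234))


@pytest.fixture
def random_volume(rng):
    """10^3 volume of positive intensities in [20, 220]."""
    return Volume(rng.uniform(20.0, 220.0, size=(10, 10, 10)))


@pytest.fixture
def noisy_phantom_24():
    """24^3 phantom with gamma=0.5 speckle at sigma=5, seed 42."""
    clean = make_phantom(default_phantom_spec((24, 24, 24)))
    return add_speckle(clean, NoiseParams(gamma=0.5, sigma=5.0, seed=42))
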