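import numpy as np
import pytest

from lambertw import tukey_h


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def heavy_sample(rng):
    """Standardized Tukey-h sample, delta = 1/3, N = 1000 (location/scale known)."""
    return np.asarray(tukey_h(0.0, 1.0, 1 / 3).sample(1000, rng))


@pytest.fixture
def gaussian_sample(rng):
    return rng.standard_normal(1000)
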