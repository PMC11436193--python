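import numpy as np
import pytest

from veinfeat.filterbank import FilterBankConfig, build_bank
from veinfeat.network import LogGaborNet
from veinfeat.synth import SyntheticSpec, make_arrays


@pytest.fixture(scope="session")
def default_config():
    return FilterBankConfig()


@pytest.fixture(scope="session")
def default_bank(default_config):
    return build_bank(default_config)


@pytest.fixture(scope="session")
def small_config():
    return FilterBankConfig(n_scales=2, n_orientations=4, image_shape=(8, 8))


@pytest.fixture(scope="session")
def small_bank(small_config):
    return build_bank(small_config)


@pytest.fixture(scope="session")
def synth_dataset():
    """The default synthetic benchmark: 20 classes x 6 samples, 32x32."""
    return make_arrays(SyntheticSpec())


@pytest.fixture(scope="session")
def fitted_net(synth_dataset):
    X, _ = synth_dataset
    return LogGaborNet().fit(X[:30])


def grating(shape, wavelength, angle, phase=0.0):
    """Plane-wave grating with wave-vector at ``angle`` (radians)."""
    rows, cols = shape
    y, x = np.mgrid[0:rows, 0:cols]
    f = 1.0 / wavelength
    return np.cos(2 * np.pi * f * (x * np.cos(angle) + y * np.sin(angle))
                  + phase)
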