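import numpy as np
import pytest

from ramanmp.simulate import SimConfig, make_reference
from ramanmp.spectra_io import MeasurementSet, Spectrum


@pytest.fixture(scope="session")
def small_cfg():
    """Coarse-grid, few-spectra simulator configuration for fast tests."""
    return SimConfig(grid_step=4.0, n_spectra=60)


@pytest.fixture(scope="session")
def small_ref(small_cfg):
    return make_reference(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_measurement():
    """Tiny deterministic measurement: 4 spectra on a 0..40 cm^-1-style grid."""
    shifts = np.linspace(400.0, 800.0, 41)
    rows = np.vstack([np.full(41, float(i)) for i in range(1, 5)])
    return MeasurementSet(shifts, rows, point_id="C1", repeat=2)


def gaussian_spectrum(center, sigma, amplitude, shifts=None):
    if shifts is None:
        shifts = np.arange(400.0, 4001.0)
    y = amplitude * np.exp(-0.5 * ((shifts - center) / sigma) ** 2)
    return Spectrum(shifts, y)
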