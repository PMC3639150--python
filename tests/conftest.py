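import numpy as np
import pytest

import zerocross as zc
from zerocross import simulate as sim


@pytest.fixture(scope="session")
def grid():
    return zc.default_grid()


@pytest.fixture(scope="session")
def pure_clindamycin(grid):
    """Noiseless clindamycin-like spectrum at the reference fixed level."""
    return zc.species_spectrum(zc.CLINDAMYCIN_LIKE, sim.CLINDAMYCIN_FIXED, grid)


@pytest.fixture(scope="session")
def pure_tretinoin(grid):
    """Noiseless tretinoin-like spectrum at the reference fixed level."""
    return zc.species_spectrum(zc.TRETINOIN_LIKE, sim.TRETINOIN_FIXED, grid)


@pytest.fixture(scope="session")
def clin_design():
    return sim.generate_design("clindamycin_calibration")


@pytest.fixture(scope="session")
def tret_design():
    return sim.generate_design("tretinoin_calibration")


@pytest.fixture(scope="session")
def clin_calib_spectra(clin_design, grid):
    """Noiseless 8-level clindamycin calibration mixtures."""
    return sim.generate_spectrum_set(clin_design, grid=grid)


@pytest.fixture(scope="session")
def tret_calib_spectra(tret_design, grid):
    return sim.generate_spectrum_set(tret_design, grid=grid)


@pytest.fixture(scope="session")
def noiseless_calibrations():
    """Full noiseless two-analyte calibration (first order, 20 nm)."""
    return zc.calibrate_synthetic_system(order=1, delta_lambda_nm=20.0, n_series=1)


def gaussian_spectrum(center=364.0, width=20.0, amplitude=1.0, grid=None):
    g = zc.default_grid() if grid is None else np.asarray(grid, float)
    return zc.Spectrum(
        g, amplitude * np.exp(-((g - center) ** 2) / (2 * width**2)), "gaussian"
    )
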