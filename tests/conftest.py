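import numpy as np
import pytest

from svim.optics import OpticalConfig, compute_lf_psf
from svim.phantoms import make_nuclei_timeseries
from svim.stacks import GridSpec


@pytest.fixture(scope="session")
def wave_psf_32():
    """Small wave-optics PSF: 32x/0.8 NA, 9x9 lenslets, 7 planes."""
    cfg = OpticalConfig(magnification=32.0, numerical_aperture=0.8,
                        z_planes=tuple(np.arange(-24.0, 24.1, 8.0)),
                        lenslet_grid=(9, 9), supersampling=5)
    return compute_lf_psf(cfg)


@pytest.fixture(scope="session")
def geo_psf_20():
    """Fast geometric-model PSF: 20x/0.5 NA, 9x9 lenslets, 9 planes."""
    cfg = OpticalConfig(magnification=20.0, numerical_aperture=0.5,
                        z_planes=tuple(np.arange(-40.0, 40.1, 10.0)),
                        lenslet_grid=(9, 9), supersampling=3, psf_model="geometric")
    return compute_lf_psf(cfg)


@pytest.fixture(scope="session")
def activity_grid():
    return GridSpec((24, 96, 96), (2.5, 1.25, 1.25))


@pytest.fixture(scope="session")
def nuclei_phantom(activity_grid):
    """50 well-separated active nuclei, 100 frames at 1 volume/s."""
    return make_nuclei_timeseries(50, 100, 1.0, 1.5, 0.1, 100.0, 100.0,
                                  activity_grid, seed=11, silent_fraction=0.0,
                                  min_separation=12.0)
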