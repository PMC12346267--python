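import numpy as np
import pytest

from pactherm import (TISSUE_CALIBRATION, build_geometry, build_grid,
                      make_phantom)


@pytest.fixture(scope="session")
def geo16():
    return build_geometry({"n_elements": 16})


@pytest.fixture(scope="session")
def geo64():
    return build_geometry({"n_elements": 64})


@pytest.fixture(scope="session")
def grid32():
    return build_grid(32, 32, 0.3)


@pytest.fixture(scope="session")
def tissue_calib():
    return TISSUE_CALIBRATION


@pytest.fixture(scope="session")
def point_phantom(geo64):
    """Single off-centre point absorber on a 129x129, 0.15-mm grid."""
    grid = build_grid(129, 129, 0.15)
    return make_phantom(
        [{"center": (2.1, -1.5), "radius": 0.05, "amplitude": 1.0, "name": "pt"}],
        grid, geo64)


@pytest.fixture(scope="session")
def smooth_image():
    """Band-limited random texture used by registration tests."""
    from scipy import ndimage
    rng = np.random.default_rng(7)
    return ndimage.gaussian_filter(rng.normal(size=(96, 96)), 3)
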