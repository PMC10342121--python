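import numpy as np
import pytest

from xanthomap.basis import make_default_basis
from xanthomap.synthetic import RetinaGeometry


@pytest.fixture(scope="session")
def basis():
    return make_default_basis()


@pytest.fixture(scope="session")
def equal_basis():
    """Basis with equal cross-sections at both lasers: estimation is unbiased."""
    return make_default_basis(
        {
            "cross_sections": {
                "lut_488": 1.0,
                "zea_488": 1.0,
                "lut_514": 1.0,
                "zea_514": 1.0,
            }
        }
    )


@pytest.fixture(scope="session")
def small_geometry():
    """Scaled-down retina geometry for fast map tests (20x20 pixels)."""
    return RetinaGeometry(
        foveola_diameter_mm=0.1,
        fovea_diameter_mm=0.28,
        parafovea_diameter_mm=0.5,
        transition_width_mm=0.05,
        map_extent_mm=0.8,
        pixel_size_um=40.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230627)
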