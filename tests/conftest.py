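import numpy as np
import pytest

from phosphenes.geometry import Grid, ImplantType, SubjectGeometry
from phosphenes.axon_map import build_axon_map


@pytest.fixture(scope="session")
def subject4():
    """Geometry of the most-sampled implanted subject (6×10 array)."""
    return SubjectGeometry(
        implant_type=ImplantType.ARGUS_II,
        array_center=(-1807.0, 401.0),
        array_rotation=-22.1,
        optic_disc_center=(16.3, 2.37),
        subject_id="4",
    )


@pytest.fixture(scope="session")
def small_map(subject4):
    """Reduced-density axon map for fast tests."""
    return build_axon_map(subject4, phi0_samples=200, step=0.5)


@pytest.fixture(scope="session")
def dense_map(subject4):
    return build_axon_map(subject4, phi0_samples=500, step=0.25)


@pytest.fixture(scope="session")
def fit_grid():
    """Coarse raster covering the implant region, for fitting tests."""
    return Grid((-24.0, 6.0), (-14.0, 14.0), 0.5)


@pytest.fixture(scope="session")
def render_grid():
    return Grid((-24.0, 10.0), (-16.0, 16.0), 0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
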