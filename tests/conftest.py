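import numpy as np
import pytest

import rvspect as rv


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    """A 24^3 emulated grid with 4.42 mm voxels."""
    return rv.VolumeGrid(np.zeros((24, 24, 24)), (4.42, 4.42, 4.42))


@pytest.fixture
def small_geometry():
    return rv.AcquisitionGeometry.circular(
        n_views=20,
        orbit_radius=80.0,
        pixel_size=(4.42, 4.42),
        detector_shape=(24, 24),
        time_per_view=45.0,
    )


@pytest.fixture(scope="session")
def tiny_organ_study():
    """Desk-scale organ phantom shared by the slower reconstruction tests."""
    return rv.organ_study(
        matrix_shape=(32, 32, 24),
        emulated_factor=(1, 1, 1),
        n_views=20,
        unlabeled_slices=0,
        label_air=True,
    )
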