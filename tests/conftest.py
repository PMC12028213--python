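import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # naive_ibsi oracle helpers

from robustrad.aif import WeinmannAIF
from robustrad.core import Mask3D
from robustrad.phantom import AcquisitionSpec, LesionTruth, make_lesion_mask

#: a small grid that keeps every simulation fast while leaving the
#: 2-voxel perturbation margin intact
SMALL_GRID = (24, 24, 12)
SMALL_SPACING = (1.0, 1.0, 3.0)


@pytest.fixture(scope="session")
def aif():
    return WeinmannAIF()


@pytest.fixture(scope="session")
def small_acq_noiseless():
    return AcquisitionSpec(grid_shape=SMALL_GRID, voxel_spacing=SMALL_SPACING,
                           noise_sigma=0.0)


@pytest.fixture(scope="session")
def small_acq_noisy():
    return AcquisitionSpec(grid_shape=SMALL_GRID, voxel_spacing=SMALL_SPACING,
                           noise_sigma=0.02)


@pytest.fixture(scope="session")
def canonical_truth():
    """The reference lesion used throughout the recovery tests."""
    return LesionTruth(
        class_label="malignant",
        ktrans=0.2, ve=0.3, vp=0.05,
        d_true=1.0e-3, d_star=10e-3, f_perf=0.15,
        center=(12, 12, 6), radii=(6.0, 6.0, 7.0),
    )


@pytest.fixture
def sphere_mask():
    """Ellipsoidal mask on the small grid with the required border margin."""
    return make_lesion_mask(SMALL_GRID, SMALL_SPACING, (12, 12, 6), (6.0, 6.0, 7.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
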