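import numpy as np
import pytest

from regiq.geometry import RigidTransform
from regiq.mvd import normalization_factors
from regiq.phantom import brain_roi, make_case, make_head_phantom


@pytest.fixture(scope="session")
def volume():
    """Small head phantom shared across tests (32^3 voxels at 3 mm)."""
    return make_head_phantom(1, grid_size=32, spacing=3.0, volume_id="T01")


@pytest.fixture(scope="session")
def noiseless_case(volume):
    """Reference pair rendered at the identity pose with no noise."""
    return make_case(volume, RigidTransform.identity(), noise_sd=0.0, seed=0,
                     case_id="T01_F01", subject_id="T01")


@pytest.fixture(scope="session")
def roi3(volume):
    return brain_roi(volume)


@pytest.fixture(scope="session")
def nf(volume, roi3):
    return normalization_factors(roi3, volume.isocenter, sample_spacing=3.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
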