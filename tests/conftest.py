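import numpy as np
import pytest

from garange.cohort import CohortConfig, VoxelGrid, build_patient
from garange.projector import SinogramGeometry, SystemModel
from garange.range_kernel import make_kernel


@pytest.fixture(scope="session")
def ga_kernel():
    """Ga-68 range kernel at the default clinical voxel spacing."""
    return make_kernel("Ga-68", (2.73, 2.73, 2.80), n_samples=200_000, seed=42)


@pytest.fixture(scope="session")
def f18_kernel():
    return make_kernel("F-18", (2.73, 2.73, 2.80), n_samples=200_000, seed=42)


@pytest.fixture(scope="session")
def small_patient():
    """Default-geometry digital patient on the desk-scale grid."""
    return build_patient(CohortConfig(), seed=5, patient_index=2)


@pytest.fixture(scope="session")
def small_system():
    return SystemModel(geometry=SinogramGeometry(60, 64, 2.73, 16))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
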