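import numpy as np
import pytest

from cectkit import biomechanics as bm
from cectkit import phantom as ph


@pytest.fixture(scope="session")
def uptake_default() -> ph.UptakeTruth:
    """Reference uptake kinetics of the cationic-particle cohort."""
    return ph.UptakeTruth()


@pytest.fixture(scope="session")
def small_spec() -> ph.PhantomSpec:
    """A coarse, fast plug phantom for unit tests (noiseless, untilted)."""
    return ph.PhantomSpec(
        plug_diameter_mm=3.0,
        cartilage_thickness_mm=1.2,
        bone_thickness_mm=0.6,
        voxel_size_um=100.0,
        margin_plane_vox=2,
    )


@pytest.fixture(scope="session")
def geometry() -> bm.IndentationGeometry:
    return bm.IndentationGeometry(cartilage_thickness_mm=2.0)


@pytest.fixture(scope="session")
def relax_record(geometry):
    """Noiseless stress-relaxation record from the default viscoelastic truth."""
    record, truth = ph.generate_stress_relaxation(ph.ViscoTruth(), geometry)
    return record, truth


@pytest.fixture(scope="session")
def sinusoid_record(geometry):
    record, truth = ph.generate_sinusoid(ph.ViscoTruth(), geometry)
    return record, truth


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
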