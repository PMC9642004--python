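import numpy as np
import pytest

from emval.structure_map_io import DensityMap
from emval.synthetic_fixtures import PerturbationSpec, make_helix, make_test_pair, perturb


@pytest.fixture(scope="session")
def helix30():
    return make_helix(30)


@pytest.fixture(scope="session")
def helix30_map(helix30):
    """Noiseless simulated map of the 30-residue helix at 3 A."""
    density, _ = make_test_pair(helix30, 3.0, noise_sigma=0.0, seed=0)
    return density


@pytest.fixture(scope="session")
def shifted_helix(helix30):
    """Residues 10-14 displaced 3 A in a generic (non-axial) direction."""
    return perturb(helix30, PerturbationSpec("segment_shift", 10, 14, 3.0, seed=42))


@pytest.fixture()
def noise_map_64():
    rng = np.random.default_rng(7)
    return DensityMap(
        data=rng.normal(size=(64, 64, 64)).astype(np.float32),
        voxel_size=(1.0, 1.0, 1.0),
    )


def make_noise_map(seed, n=64, sigma=1.0, voxel=1.0):
    rng = np.random.default_rng(seed)
    return DensityMap(
        data=(sigma * rng.normal(size=(n, n, n))).astype(np.float32),
        voxel_size=(voxel, voxel, voxel),
    )
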