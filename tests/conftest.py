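import numpy as np
import pytest

from dockrl.fixtures import FixtureSpec, make_fixture
from dockrl.structures import default_channel_map, element_channel_map
from dockrl.voxel import BoxSpec, LigandPose, make_box


@pytest.fixture(scope="session")
def cu_map():
    return default_channel_map(("CU",))


@pytest.fixture(scope="session")
def so4_map():
    return default_channel_map(("S", "O"))


@pytest.fixture(scope="session")
def tiny_cu_map():
    """Compact element map (5 protein classes + CU) for fast desk-scale runs."""
    return element_channel_map(("CU",))


@pytest.fixture(scope="session")
def cu_record(cu_map):
    record, _ = make_fixture(FixtureSpec(n_protein_atoms=40, seed=7), cu_map)
    return record


@pytest.fixture(scope="session")
def cu_pdb_text(cu_map):
    _, text = make_fixture(FixtureSpec(n_protein_atoms=40, seed=7), cu_map)
    return text


@pytest.fixture(scope="session")
def so4_record(so4_map):
    record, _ = make_fixture(
        FixtureSpec(n_protein_atoms=40, ligand_kind="sulfate_like", seed=11), so4_map
    )
    return record


@pytest.fixture(scope="session")
def cu_box(cu_record, cu_map):
    box, true_pose = make_box(cu_record, BoxSpec(min_protein_atoms=10), cu_map, rng=3)
    return box, true_pose


def random_sulfate_pose(rng, spread=5.0):
    """A random (not necessarily tetrahedral) 1 S + 4 O pose."""
    coords = rng.uniform(-spread, spread, size=(5, 3))
    return LigandPose(coords=coords, elements=("S", "O", "O", "O", "O"))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
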