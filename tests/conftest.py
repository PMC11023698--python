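import numpy as np
import pytest

from geomsite import (ModelConfig, NormalizationStats, SyntheticSpec,
                      generate_backbone, generate_dataset)
from geomsite.structure_io import ProteinStructure, write_structure
from geomsite.training import encode_synthetic_dataset


def rigid_transform(rng):
    """Random rotation matrix + translation vector."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.normal(0, 20, 3)
    return R, t


@pytest.fixture(scope="session")
def helix():
    return generate_backbone(20, "helix", seed=11)


@pytest.fixture(scope="session")
def mixed_structure():
    return generate_backbone(60, "mixed", seed=7, noise=0.05)


@pytest.fixture(scope="session")
def small_dataset():
    """30 synthetic proteins with 3 partially-masked tasks."""
    return generate_dataset(SyntheticSpec(n_proteins=30, length_range=(30, 60), seed=3))


@pytest.fixture(scope="session")
def small_encoded(small_dataset):
    return encode_synthetic_dataset(small_dataset)


@pytest.fixture(scope="session")
def onehot_stats():
    return NormalizationStats(np.zeros(20), np.ones(20))


@pytest.fixture
def gag_pdb(tmp_path):
    """Minimal Gly-Ala-Gly PDB with ideal geometry; Ala has a CB atom."""
    base = generate_backbone(5, "helix", seed=1)
    coords = base.coords[:3].copy()
    # Gly residues carry no sidechain: R must coincide with CA
    coords[0, 4] = coords[0, 1]
    coords[2, 4] = coords[2, 1]
    st = ProteinStructure(chain_id="A", sequence="GAG", coords=coords,
                          residue_ids=["1", "2", "3"])
    path = tmp_path / "gag.pdb"
    write_structure(st, str(path))
    return path, st
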