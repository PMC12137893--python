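import numpy as np
import pytest

from nsalign.structio import ChainStructure, Superposition
from nsalign.synthetic import make_ground_truth_pair, make_helix_chain


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Proper rotation from the QR decomposition of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def identity_sup():
    return Superposition.identity()


@pytest.fixture
def helix40():
    return make_helix_chain(40, seed=1)


@pytest.fixture
def cp_pair():
    """40-residue helix vs its circular permutation at 20, noiseless."""
    return make_ground_truth_pair(40, "circular", 20, sigma=0.0, seed=1)


@pytest.fixture
def tiny_chain():
    coords = np.array([
        [0.0, 0.0, 0.0],
        [3.8, 0.0, 0.0],
        [3.8, 3.8, 0.0],
        [0.0, 3.8, 3.8],
        [1.0, 1.0, 5.0],
    ])
    return ChainStructure("A", [1, 2, 3, 4, 5], [""] * 5, "AGHKL", coords)


MINIMAL_PDB = """\
HEADER    TEST STRUCTURE
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       4.000   5.000   6.000  1.00  0.00           C
ATOM      4  CA  SER A   3       7.000   8.000   9.500  1.00  0.00           C
TER
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       1.000   1.000   1.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       2.000   2.000   2.000  1.00  0.00           C
ATOM      3  CA  SER A   3       3.000   3.000   3.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       9.000   9.000   9.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       8.000   8.000   8.000  1.00  0.00           C
ATOM      3  CA  SER A   3       7.000   7.000   7.000  1.00  0.00           C
ENDMDL
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def two_model_pdb(tmp_path):
    p = tmp_path / "two_model.pdb"
    p.write_text(TWO_MODEL_PDB)
    return p
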