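import numpy as np
import pytest

import foldscan as fs
from foldscan.sequence_domains import AMINO_ACIDS


@pytest.fixture(scope="session")
def myo7a_map():
    return fs.default_myo7a_domain_map()


@pytest.fixture
def toy_sequence():
    return fs.ProteinSequence(id="toy", residues="ALDG")


@pytest.fixture
def toy_ddg(toy_sequence):
    """4×20 matrix: zeros except a few hand-set cells; identity column zero."""
    values = np.zeros((4, 20))
    values[0, AMINO_ACIDS.index("D")] = 2.0  # A1D
    values[1, AMINO_ACIDS.index("P")] = 1.0  # L2P
    values[2, AMINO_ACIDS.index("K")] = -1.5  # D3K
    return fs.DdgMatrix(protein_id="toy", wild_type="ALDG", values=values)


@pytest.fixture(scope="session")
def small_scan():
    """A full synthetic scan (L=120): sequence, structure, burial, noise-free ΔΔG."""
    length, seed = 120, 7
    seq = fs.random_protein_sequence(length, seed)
    structure = fs.simulate_structure(length, seed, sequence=seq)
    burial = fs.burial_profile(structure, fs.SurrogateParams())
    ddg = fs.simulate_ddg_matrix(seq, burial, identity_noise_sd=0.0, seed=seed)
    return seq, structure, burial, ddg


@pytest.fixture
def pdb_fragment(tmp_path):
    """Hand-written three-residue PDB fragment (Ala-Gly-Leu) with Cβ where present."""
    text = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  CA  GLY A   2       5.258   0.000   0.000  1.00  0.00           C
ATOM      5  CA  LEU A   3       9.058   0.000   0.000  1.00  0.00           C
ATOM      6  CB  LEU A   3       9.600   1.400   0.200  1.00  0.00           C
END
"""
    path = tmp_path / "frag.pdb"
    path.write_text(text)
    return path
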