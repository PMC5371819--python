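import numpy as np
import pytest

from swiveldyn import synthetic
from swiveldyn.structures import EnsembleAlignment

# hand-written 6-residue chain with: an altloc pair on residue 3's CB
# (A occ 0.60 at x=3.5, B occ 0.40 at x=9.9), a PEP ligand, and a water
# that must be excluded on reading
TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00 10.00           C
ATOM      3  CA  GLY A   2       2.000   1.000   0.000  1.00 10.00           C
ATOM      4  CA  SER A   3       3.000   2.000   1.000  1.00 10.00           C
ATOM      5  CB ASER A   3       3.500   2.500   1.000  0.60 10.00           C
ATOM      6  CB BSER A   3       9.900   9.900   9.900  0.40 10.00           C
ATOM      7  CA  HIS A   4       4.000   3.000   2.000  1.00 10.00           C
ATOM      8  NE2 HIS A   4       4.500   3.500   2.500  1.00 10.00           N
ATOM      9  CA  GLU A   5       5.000   4.000   3.000  1.00 10.00           C
ATOM     10  CA  LEU A   6       6.000   5.000   4.000  1.00 10.00           C
HETATM   11  O2  PEP A 901       7.000   6.000   5.000  1.00 10.00           O
HETATM   12  P   PEP A 901       7.500   6.500   5.500  1.00 10.00           P
HETATM   13  O   HOH A 902       8.000   8.000   8.000  1.00 10.00           O
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture
def tiny_model(tiny_pdb):
    from swiveldyn.structures import read_structure
    return read_structure(tiny_pdb, chain="A")


def make_ensemble_from_coords(coord_list, fitted=False):
    coords = np.stack(coord_list)
    n, m, _ = coords.shape
    return EnsembleAlignment([f"m{i}" for i in range(n)],
                             [(r + 1, "") for r in range(m)], coords,
                             fitted=fitted)


@pytest.fixture
def chain_coords():
    return synthetic.chain_walk_coords(30, seed=11)
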