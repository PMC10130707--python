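import numpy as np
import pytest

from knotph.rips_persistence import PersistenceDiagram


PDB_THREE_RESIDUES = """\
ATOM      1  N   ALA A   1      -1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       2.800   0.000   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      6  C   GLY A   2       4.800   0.000   0.000  1.00  0.00           C
ATOM      7  N   SER A   3       6.600   0.000   0.000  1.00  0.00           N
ATOM      8  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
ATOM      9  C   SER A   3       8.600   0.000   0.000  1.00  0.00           C
END
"""

PDB_ALTLOC = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.40  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def pdb_three_residues():
    return PDB_THREE_RESIDUES


@pytest.fixture
def pdb_altloc():
    return PDB_ALTLOC


@pytest.fixture
def unit_square():
    return np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)


@pytest.fixture
def hexagon():
    t = np.linspace(0, 2 * np.pi, 7)[:-1]
    return np.stack([np.cos(t), np.sin(t), np.zeros(6)], axis=1)


def random_diagram(rng, max_points=8):
    n = int(rng.integers(0, max_points + 1))
    b = rng.uniform(0, 5, n)
    p = rng.uniform(0.05, 5, n)
    pairs = np.stack([b, b + p], axis=1) if n else np.empty((0, 2))
    return PersistenceDiagram(pairs=pairs, max_scale=12.0)
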