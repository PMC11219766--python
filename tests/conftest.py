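import numpy as np
import pytest

from frasebot.fixtures import FixtureSpec, make_frase_set, make_toy_complex


@pytest.fixture(scope="session")
def frase_set_small():
    """30 synthetic true FRASEs shared across tests (read-only)."""
    return make_frase_set(30, seed=1)


@pytest.fixture(scope="session")
def toy_complex():
    cx, truth = make_toy_complex(FixtureSpec(seed=5))
    return cx, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


TOY_PDB = """\
ATOM      1  N   ALA A   1      -1.460   0.000   0.600  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       0.900   1.200   0.300  1.00  0.00           C
ATOM      4  O   ALA A   1       2.100   1.100   0.400  1.00  0.00           O
ATOM      5  CB  ALA A   1       0.500  -0.900  -1.100  1.00  0.00           C
ATOM      6  N   GLY A   2       8.540   0.000   0.600  1.00  0.00           N
ATOM      7  CA  GLY A   2      10.000   0.000   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2      10.900   1.200   0.300  1.00  0.00           C
ATOM      9  O   GLY A   2      12.100   1.100   0.400  1.00  0.00           O
ATOM     10  N   SER A   3       3.540   8.660   0.600  1.00  0.00           N
ATOM     11  CA ASER A   3       5.000   8.660   0.000  0.40  0.00           C
ATOM     12  CA BSER A   3       5.000   8.660   0.500  0.60  0.00           C
ATOM     13  C   SER A   3       5.900   9.860   0.300  1.00  0.00           C
ATOM     14  O   SER A   3       7.100   9.760   0.400  1.00  0.00           O
ATOM     15  OG  SER A   3       4.500   7.760  -1.100  1.00  0.00           O
TER      16
HETATM   17  C1  BNZ X 901       4.000   3.000   5.000  1.00  0.00           C
HETATM   18  C2  BNZ X 901       5.390   3.000   5.000  1.00  0.00           C
HETATM   19  C3  BNZ X 901       6.090   3.000   6.210  1.00  0.00           C
HETATM   20  C4  BNZ X 901       5.390   3.000   7.410  1.00  0.00           C
HETATM   21  C5  BNZ X 901       4.000   3.000   7.410  1.00  0.00           C
HETATM   22  C6  BNZ X 901       3.300   3.000   6.210  1.00  0.00           C
HETATM   23  O   HOH W1001       0.000   5.000   5.000  1.00  0.00           O
HETATM   24  O   HOH W1002       1.000   6.000   5.000  1.00  0.00           O
END
"""


@pytest.fixture()
def toy_pdb_path(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return str(p)
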