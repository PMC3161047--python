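import textwrap

import pytest

from ppicontacts.structure import read_structure


TWO_CHAIN_PDB = textwrap.dedent("""\
    REMARK   2 RESOLUTION.    1.80 ANGSTROMS.
    REMARK   3   R VALUE            (WORKING SET) : 0.195
    ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00 10.00           N
    ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00 10.00           C
    ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00 10.00           C
    ATOM      4  O   GLY A   1       3.100   1.500   0.500  1.00 10.00           O
    ATOM      5  N   ALA A   2       1.300   2.500   0.000  1.00 10.00           N
    ATOM      6  CA  ALA A   2       1.700   3.900   0.000  1.00 10.00           C
    ATOM      7  C   ALA A   2       0.800   4.900   0.700  1.00 10.00           C
    ATOM      8  O   ALA A   2      -0.300   4.600   1.200  1.00 10.00           O
    ATOM      9  CB  ALA A   2       1.900   4.400  -1.400  1.00 10.00           C
    TER
    ATOM     10  N   SER B   1       6.000   0.000   0.000  1.00 10.00           N
    ATOM     11  CA  SER B   1       7.400   0.000   0.000  1.00 10.00           C
    ATOM     12  C   SER B   1       8.000   1.400   0.000  1.00 10.00           C
    ATOM     13  O   SER B   1       9.200   1.500   0.000  1.00 10.00           O
    ATOM     14  CB  SER B   1       7.900  -0.800  -1.200  1.00 10.00           C
    ATOM     15  OG  SER B   1       7.500  -2.100  -1.100  1.00 10.00           O
    END
    """)


@pytest.fixture
def two_chain_structure():
    return read_structure(TWO_CHAIN_PDB, entry_id="TOY2")


@pytest.fixture
def two_chain_pdb_text():
    return TWO_CHAIN_PDB
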