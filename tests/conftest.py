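import numpy as np
import pytest

import mirrorsep as ms

# A 5-residue backbone written out by hand in fixed PDB columns (ideal
# helix geometry).  Used to exercise the parser on literal text rather
# than on anything produced by the package's own writer.
FIVE_RESIDUE_PDB = """\
ATOM      1   N  ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3   C  ALA A   1       2.009   1.422   0.000  1.00  0.00           C
ATOM      4   O  ALA A   1       2.910   1.749   0.773  1.00  0.00           O
ATOM      5   N  GLY A   2       1.463   2.263  -0.872  1.00  0.00           N
ATOM      6  CA  GLY A   2       1.899   3.650  -0.974  1.00  0.00           C
ATOM      7   C  GLY A   2       1.768   4.370   0.364  1.00  0.00           C
ATOM      8   O  GLY A   2       2.689   5.059   0.802  1.00  0.00           O
ATOM      9   N  SER A   3       0.618   4.205   1.008  1.00  0.00           N
ATOM     10  CA  SER A   3       0.364   4.838   2.297  1.00  0.00           C
ATOM     11   C  SER A   3       1.421   4.443   3.323  1.00  0.00           C
ATOM     12   O  SER A   3       1.961   5.294   4.030  1.00  0.00           O
ATOM     13   N  ALA A   4       1.711   3.149   3.398  1.00  0.00           N
ATOM     14  CA  ALA A   4       2.704   2.639   4.337  1.00  0.00           C
ATOM     15   C  ALA A   4       4.057   3.309   4.126  1.00  0.00           C
ATOM     16   O  ALA A   4       4.701   3.745   5.081  1.00  0.00           O
ATOM     17   N  VAL A   5       4.484   3.388   2.870  1.00  0.00           N
ATOM     18  CA  VAL A   5       5.761   4.005   2.531  1.00  0.00           C
ATOM     19   C  VAL A   5       5.830   5.442   3.035  1.00  0.00           C
ATOM     20   O  VAL A   5       6.820   5.851   3.640  1.00  0.00           O
TER
END
"""

THREE_RESIDUE_PDB = "".join(
    line + "\n" for line in FIVE_RESIDUE_PDB.splitlines()
    if line.startswith(("TER", "END")) or (line.startswith("ATOM") and int(line[22:26]) <= 3)
)

#: a short case-annotated two-helix bundle used wherever a full-size
#: domain would be too slow
MINI_BUNDLE_SEQ = "AELKQRMAELKQRMAELKQRM" + "gnstd" + "AELKQRMAELKQRMAELKQRM"


@pytest.fixture(scope="session")
def tables():
    return ms.default_tables()


@pytest.fixture(scope="session")
def helix20():
    dihed = np.tile([-57.0, -47.0, 180.0], (20, 1))
    return ms.build_chain("A" * 20, dihed, model_id="helix20")


@pytest.fixture(scope="session")
def mini_reference():
    spec = ms.EnsembleSpec(sequence=MINI_BUNDLE_SEQ, seed=3)
    return ms.build_reference(spec)


@pytest.fixture()
def five_res_pdb(tmp_path):
    path = tmp_path / "five.pdb"
    path.write_text(FIVE_RESIDUE_PDB)
    return path


@pytest.fixture()
def three_res_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


def random_dihedral_model(rng, n=12, model_id="rand"):
    """Short chain with uniform-random phi/psi; shared helper for tests."""
    d = np.column_stack([
        rng.uniform(-179.0, 179.0, size=n),
        rng.uniform(-179.0, 179.0, size=n),
        np.full(n, 180.0),
    ])
    return ms.build_chain("A" * n, d, model_id=model_id)
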