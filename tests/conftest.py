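import numpy as np
import pytest

from allokit import synth
from allokit.structure import CaTrace, extract_ca_trace


THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      6  C   GLY A   2       5.504   2.711   0.000  1.00  0.00           C
ATOM      7  N   SER A   3       6.131   3.880   0.000  1.00  0.00           N
ATOM      8  CA  SER A   3       7.583   3.947   0.000  1.00  0.00           C
ATOM      9  OG  SER A   3       8.109   5.293   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def three_residue_pdb():
    return THREE_RESIDUE_PDB


@pytest.fixture(scope="session")
def toy_dimer():
    """Default toy homodimer with its ground-truth labels (seed 0)."""
    spec = synth.ToyDimerSpec(seed=0)
    model, labels = synth.make_toy_dimer(spec)
    return spec, model, labels


@pytest.fixture(scope="session")
def toy_dimer_covariance(toy_dimer):
    spec, model, labels = toy_dimer
    cov = synth.make_dimer_covariance(model, labels, spec=spec)
    return cov


@pytest.fixture(scope="session")
def toy_dimer_trace(toy_dimer):
    _, model, _ = toy_dimer
    return extract_ca_trace(model)


def linear_ca_trace(n: int, spacing: float = 3.8) -> CaTrace:
    pos = np.zeros((n, 3))
    pos[:, 0] = spacing * np.arange(n)
    return CaTrace(positions=pos,
                   residue_index_map=[("A", i + 1, "") for i in range(n)])
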