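import pytest

from anchordock.fixtures import make_toy_system
from anchordock.sampling import SamplingConfig


@pytest.fixture(scope="session")
def toy_system():
    return make_toy_system(seed=1)


@pytest.fixture()
def fast_sampling():
    # scaled-down sampling for unit tests; defaults are exercised in
    # the acceptance suite
    return SamplingConfig(n_max=20, minimize_steps=40, seed=7)


ALANINE_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.161  -4.922  1.00  0.00           C
ATOM      4  O   ALA A   1      13.339   7.616  -5.855  1.00  0.00           O
ATOM      5  CB  ALA A   1      10.440   6.226  -4.219  1.00  0.00           C
END
"""


@pytest.fixture()
def alanine_pdb():
    return ALANINE_PDB
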