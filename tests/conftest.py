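import numpy as np
import pytest

from conservscape import default_model, score_alignment
from conservscape.seqsim import SimulationConfig, simulate_dataset

#: the test-bed study condition: 60 taxa, 300 sites, 10% conserved, seed 7
TWO_RATE_CONFIG = SimulationConfig(
    n_taxa=60, site_blocks=((30, 0.1), (270, 1.5)), seed=7
)
GAMMA_CONFIG = SimulationConfig(
    n_taxa=60, site_blocks=None, alpha_true=0.5, n_sites=300, seed=7
)


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def two_rate_dataset():
    """60-taxon, 300-site alignment with 30 sites frozen at rate 0.1."""
    return simulate_dataset(TWO_RATE_CONFIG)


@pytest.fixture(scope="session")
def two_rate_scores(two_rate_dataset):
    alignment, tree, _clades, _truth = two_rate_dataset
    return score_alignment(alignment, tree=tree)


@pytest.fixture(scope="session")
def gamma_dataset():
    """60-taxon, 300-site alignment with gamma(0.5) site rates."""
    return simulate_dataset(GAMMA_CONFIG)


@pytest.fixture(scope="session")
def gamma_scores(gamma_dataset):
    alignment, tree, _clades, _truth = gamma_dataset
    return score_alignment(alignment, tree=tree)


SYNTHETIC_PDB = """\
ATOM      1  N   ASP A 309      10.000  10.000  10.000  1.00 20.00           N
ATOM      2  CA  ASP A 309      11.000  10.500  10.200  1.00 21.50           C
ATOM      3  C   ASP A 309      12.000  11.000  10.400  1.00 19.75           C
ATOM      4  N   THR A 310      13.000  11.500  10.600  1.00 18.30           N
ATOM      5  CA  THR A 310      14.000  12.000  10.800  1.00 17.60           C
ATOM      6  N   GLY A 311      15.000  12.500  11.000  1.00 22.10           N
ATOM      7  CA  GLY A 311      16.000  13.000  11.200  1.00 23.40           C
ATOM      8  N   ALA A 999      17.000  13.500  11.400  1.00 25.00           N
HETATM    9 FE   HEM A 600      18.000  14.000  11.600  1.00 30.00          FE
HETATM   10  C1  HEM A 600      19.000  14.500  11.800  1.00 31.25           C
END
"""


@pytest.fixture()
def synthetic_pdb(tmp_path):
    """A tiny hand-made structure file (synthetic, not a real protein)."""
    path = tmp_path / "synthetic_model.pdb"
    path.write_text(SYNTHETIC_PDB)
    return str(path)
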