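import numpy as np
import pytest

from csgkit.fixtures import make_toy_peptide
from csgkit.grafting import load_csg_template
from csgkit.structure import Trajectory


@pytest.fixture(scope="session")
def csg_template():
    return load_csg_template()


@pytest.fixture(scope="session")
def toy_csg():
    """ALA-CSG-ALA peptide, chi_ss = +90."""
    return make_toy_peptide("ACA", include_csg_at=2)


@pytest.fixture(scope="session")
def toy_acgca():
    """Five-residue peptide with a central CSG, used where neighbors matter."""
    return make_toy_peptide("AGCGA", include_csg_at=3)


@pytest.fixture(scope="session")
def toy_plain():
    return make_toy_peptide("ACA")


@pytest.fixture
def rng():
    return np.random.default_rng(20230914)


@pytest.fixture
def single_frame(toy_csg):
    return Trajectory.from_structure(toy_csg)
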