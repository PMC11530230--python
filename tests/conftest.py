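import numpy as np
import pytest

from omegamap import default_parameter_table
from omegamap.fixtures import HELIX_PHI_PSI, build_chain


@pytest.fixture(scope="session")
def table():
    """The bundled contact-parameter table."""
    return default_parameter_table()


@pytest.fixture(scope="session")
def helix15():
    """An ideal 15-residue poly-alanine alpha-helix."""
    return build_chain([HELIX_PHI_PSI] * 15)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
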