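import numpy as np
import pytest

from rsfit import (
    RotamerLibrary,
    make_ideal_polypeptide,
    make_toy_ligand,
    synthesize_map,
)
from rsfit.dictionary import default_dictionary


@pytest.fixture(scope="session")
def helix20():
    """20-residue polyalanine ideal alpha helix."""
    return make_ideal_polypeptide("A" * 20, "helix")


@pytest.fixture(scope="session")
def helix20_map(helix20):
    return synthesize_map(helix20)


@pytest.fixture(scope="session")
def mixed_helix():
    """Ideal helix with a mix of side-chain types."""
    return make_ideal_polypeptide("ASLKDESQML", "helix")


@pytest.fixture(scope="session")
def toy_ligand():
    return make_toy_ligand()


@pytest.fixture(scope="session")
def rotamer_library():
    return RotamerLibrary.load_default()


@pytest.fixture(scope="session")
def dictionary():
    return default_dictionary()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def rmsd(a, b) -> float:
    xa = a.coords() if hasattr(a, "coords") else np.asarray(a)
    xb = b.coords() if hasattr(b, "coords") else np.asarray(b)
    return float(np.sqrt(((xa - xb) ** 2).sum(axis=1).mean()))
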