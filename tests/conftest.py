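import numpy as np
import pytest

from sbnlearn import (
    TaxonSet,
    build_support,
    enumerate_unrooted,
)
from sbnlearn._compile import CompiledCollection


@pytest.fixture(scope="session")
def taxa5():
    return TaxonSet("ABCDE")


@pytest.fixture(scope="session")
def space5(taxa5):
    return enumerate_unrooted(taxa5)


@pytest.fixture(scope="session")
def support5(space5):
    return build_support(space5)


@pytest.fixture(scope="session")
def compiled5(space5, support5):
    return CompiledCollection(space5, support5)


@pytest.fixture(scope="session")
def eight_taxon_world():
    """Enumerated 8-taxon space with its full support, built once: the
    heavier acceptance-style checks all share it."""
    taxa = TaxonSet(f"t{i}" for i in range(8))
    space = enumerate_unrooted(taxa)
    support = build_support(space)
    return {
        "taxa": taxa,
        "space": space,
        "support": support,
        "compiled": CompiledCollection(space, support),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240909)
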