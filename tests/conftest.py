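import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import cardevol as ce
from cardevol.alignment import ProteinAlignment


@pytest.fixture(scope="session")
def lg2():
    """LG model with 2 gamma categories (cheap but exercises the mixture)."""
    return ce.lg_model(alpha=1.0, ncat=2)


@pytest.fixture(scope="session")
def lg_flat():
    """LG model without rate variation."""
    return ce.lg_model(alpha=1.0, ncat=1)


@pytest.fixture(scope="session")
def tree3():
    return ce.parse_tree("((a:0.3,b:0.5):0.2,c:0.7);")


@pytest.fixture(scope="session")
def aln3():
    return ProteinAlignment([("a", "MK"), ("b", "ML"), ("c", "RK")])


@pytest.fixture(scope="session")
def tree6():
    return ce.random_tree(6, total_length=2.0, seed=11)


@pytest.fixture(scope="session")
def card_fixture():
    """The synthetic five-subfamily protein-domain dataset (session scope:
    several profile/network tests reuse it)."""
    return ce.card_family_fixture(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
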