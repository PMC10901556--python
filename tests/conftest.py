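import numpy as np
import pytest

from p53evo.asr import Alignment
from p53evo.evo_models import jtt_model
from p53evo.phylo import parse_newick


@pytest.fixture(scope="session")
def jtt_gi():
    """JTT+G+I with 2 gamma categories (cheap but heterogeneous)."""
    return jtt_model(gamma_shape=0.8, p_invariant=0.1, n_categories=2)


@pytest.fixture(scope="session")
def jtt_gi5():
    """JTT+G+I with the full 5 gamma categories."""
    return jtt_model(gamma_shape=1.0, p_invariant=0.1, n_categories=5)


@pytest.fixture
def quartet_tree():
    return parse_newick("((A:0.3,B:0.5):0.2,(C:0.4,D:0.1):0.6);")


@pytest.fixture
def quartet_alignment():
    return Alignment(["A", "B", "C", "D"], ["AC", "CW", "A-", "AX"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
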