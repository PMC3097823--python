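import numpy as np
import pytest

from mlnet.dataio import parse_newick


@pytest.fixture
def t4():
    """((A,B),(C,D)) — the 4-leaf worked example."""
    return parse_newick("((A,B),(C,D));")


@pytest.fixture
def t8():
    """(((A,B),(C,D)),((E,F),(G,H))) — the 8-leaf worked example."""
    return parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
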