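import pytest

from phylobrowse import parse_newick, simulate_yule_tree


@pytest.fixture
def basic_tree():
    """Three tips: ((A:1,B:1):1,C:2); — ultrametric, d(A,B)=2, d(A,C)=4."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def quartet():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def yule50():
    return simulate_yule_tree(50, 1.0, seed=1)
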