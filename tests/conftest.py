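import warnings

import pytest

from paralintron.trees import parse_newick


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Keep intentionally noisy paths (speciation defaults etc.) quiet."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def two_leaf_tree():
    return parse_newick("(A,B);")


@pytest.fixture
def d1d2_tree():
    """The worked gene-tree example: ((OG_A,OG_B)D2,OG_C)D1."""
    return parse_newick(
        "((OG_A,OG_B)D2[&&NHX:type=duplication],OG_C)"
        "D1[&&NHX:type=duplication];"
    )
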