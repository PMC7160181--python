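import numpy as np
import pytest

from cladediv import tree_from_string


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — the standard small worked example."""
    return tree_from_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def polytomy_tree():
    return tree_from_string("(A:1,B:1,C:1);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
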