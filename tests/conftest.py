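import numpy as np
import pytest

from clonecarto.trees import CloneTree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_timepoint_tree():
    """stem -> (A -> B, C -> D): two sub-lineages below a truncal branch."""
    tree = CloneTree()
    stem = tree.add_child(tree.root, events=("s1", "s2"), name="stem")
    a = tree.add_child(stem, events=("a",), name="A")
    tree.add_child(a, events=("b",), name="B")
    c = tree.add_child(stem, events=("c",), name="C")
    tree.add_child(c, events=("d",), name="D")
    return tree
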