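import numpy as np
import pytest

import cecaphylo as cp


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — tip depths all 2, MRCA(A,B) at depth 1."""
    return cp.parse_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def quartet_tree():
    return cp.parse_tree("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def study_dataset():
    """One fixed 155-taxon synthetic study dataset shared across tests."""
    cfg = cp.SyntheticConfig(n_taxa=155, seed=20240917)
    return cp.make_study_like_dataset(cfg)


@pytest.fixture(scope="session")
def yule200():
    """A fixed 200-tip depth-10 pure-birth tree for recovery experiments."""
    return cp.yule_tree(200, depth=10.0, seed=424242)


def random_tree(n_tips, seed, collapse_prob=0.0):
    """Random Yule topology; optionally collapse internal edges into
    polytomies with probability ``collapse_prob`` each."""
    rng = np.random.default_rng(seed)
    tree = cp.yule_tree(n_tips, depth=10.0, rng=rng)
    if collapse_prob > 0:
        for edge in list(tree.preorder_edge_iter()):
            node = edge.head_node
            if (node.parent_node is not None and not node.is_leaf()
                    and rng.random() < collapse_prob):
                edge.collapse()
    return tree
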