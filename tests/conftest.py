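import io

import numpy as np
import pytest
from skbio import TreeNode

from campart.data_io import CommunityTable


@pytest.fixture
def tiny_tree():
    return TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture
def two_clade_tree():
    """Two 10-taxon clades: within-clade tip distances < 0.1, between ~2."""
    def clade(names):
        inner = ",".join(f"{n}:0.04" for n in names)
        return f"({inner}):1.0"
    left = clade([f"L{i}" for i in range(10)])
    right = clade([f"R{i}" for i in range(10)])
    return TreeNode.read(io.StringIO(f"({left},{right});"))


@pytest.fixture
def small_table():
    return CommunityTable(["A", "B", "C"], ["s1", "s2"],
                          np.array([[1.0, 3.0], [3.0, 1.0], [0.0, 4.0]]))


def random_tree(n_tips, seed):
    from campart.community_sim import simulate_tree
    return simulate_tree(n_tips, seed=seed)


def random_dist(n, seed):
    """A random additive (tree-free) distance matrix: symmetric, hollow."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 1, size=(n, 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return d


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)
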