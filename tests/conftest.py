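import numpy as np
import pytest

from shiftpower import BDRates, simulate_bd_tree
from shiftpower.treeio import read_newick

# fixed 5-tip caterpillar with internal node ages 10, 6, 3, 1
CATERPILLAR5 = "((((a:1,b:1):2,c:3):3,d:6):4,e:10);"
# perfectly balanced 4-tip tree, internal ages 10 (root), 4, 4
BALANCED4 = "((a:4,b:4):6,(c:4,d:4):6);"


@pytest.fixture
def caterpillar5():
    return read_newick(CATERPILLAR5)


@pytest.fixture
def balanced4():
    return read_newick(BALANCED4)


@pytest.fixture(scope="session")
def random_trees():
    """Twenty seeded reconstructed birth-death trees of 10-30 tips."""
    trees = []
    rng = np.random.default_rng(2024)
    seed = 0
    while len(trees) < 20:
        seed += 1
        t = simulate_bd_tree(rng.uniform(6, 12), BDRates(0.25, 0.05), seed,
                             max_tips=60)
        if 10 <= t.n_tips <= 30:
            trees.append(t)
    return trees


def neutral_states(tree, rng=None):
    """Assign state 1 to one clade (a random internal node's tips)."""
    rng = rng or np.random.default_rng(0)
    internal = tree.internal_ids(include_root=False)
    node = int(internal[rng.integers(len(internal))])
    clade = set(tree.clade_tips(node))
    return {lab: (1 if lab in clade else 0) for lab in tree.tip_labels()}
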