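import numpy as np
import pytest

from tsbisse.simulate import sim_bd_tree, sim_mk_trait
from tsbisse.treeio import PhyloTree, TraitDataset, read_newick


@pytest.fixture
def cherry():
    return read_newick("(A:1.0,B:1.0);")


@pytest.fixture
def three_tip():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def yule5():
    return read_newick("((((A:1,B:1):1,C:2):1,D:3):1,E:4);")


def random_ultrametric_tree(n, seed, age_range=(0.5, 10.0)):
    """Random topology + branching ages by sequential joins (not a model
    draw; just a structurally valid ultrametric tree for likelihood tests)."""
    rng = np.random.default_rng(seed)
    ages = np.sort(rng.uniform(*age_range, n - 1))
    nodes = [f"T{i}" for i in range(n)]
    node_age = {f"T{i}": 0.0 for i in range(n)}
    for a in ages:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        ni, nj = nodes[i], nodes[j]
        newick = f"({ni}:{a - node_age[ni]:.12f},{nj}:{a - node_age[nj]:.12f})"
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [newick]
        node_age[newick] = a
    return read_newick(nodes[0] + ";")


def random_states(tree, seed):
    rng = np.random.default_rng(seed)
    return TraitDataset(
        {lab: int(rng.integers(0, 2)) for lab in tree.tip_labels}
    )


@pytest.fixture
def rand_tree():
    return random_ultrametric_tree


@pytest.fixture
def bd_tree_small():
    return sim_bd_tree(40, 20.0, 0.25, 0.1, seed=11)


@pytest.fixture
def bd_tree_traits(bd_tree_small):
    hist = sim_mk_trait(bd_tree_small, 0.05, 0.08, seed=12)
    return bd_tree_small, hist.traits()
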