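import itertools

import numpy as np
import pytest

from pmpi import trees as trees_mod
from pmpi.simulate import ModelParams, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """n=30, k=2 dataset in the well-separated regime (ratio 0.25)."""
    params = ModelParams(
        n=30, k=2, tau=25, sigma_g=0.1, sigma_p=0.4, pair_drop_prob=0.0, seed=7
    )
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def noisefree_dataset():
    """sigma_G = 0: genes of a pacemaker are perfectly correlated."""
    params = ModelParams(
        n=12, k=3, tau=10, sigma_g=0.0, sigma_p=0.5, pair_drop_prob=0.0, seed=3
    )
    return simulate_dataset(params)


def random_binary_tree(rng, labels):
    """Random rooted binary tree with uniform branch lengths (test helper)."""
    nodes = [
        trees_mod.TreeNode(label=lab, length=float(rng.uniform(0.1, 1.0)), children=[])
        for lab in labels
    ]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(
            trees_mod.TreeNode(
                label=None, length=float(rng.uniform(0.1, 1.0)), children=[a, b]
            )
        )
    root = trees_mod.TreeNode(label=None, length=0.0, children=nodes)
    return trees_mod.GeneTree(id="rand", root=root)


def brute_force_mast_size(t1, t2):
    """Maximum agreement-subset size by exhaustive subset enumeration."""
    shared = sorted(t1.leaf_labels() & t2.leaf_labels())
    for r in range(len(shared), 0, -1):
        for subset in itertools.combinations(shared, r):
            if trees_mod.is_agreement_subset(t1, t2, set(subset)):
                return r
    return 0


from pmpi.partdist import correctly_clustered_pair, random_partition_pair  # noqa: E402,F401
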