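import random

import dendropy
import numpy as np
import pytest

from driftshift.treeio import TraitTable


def yule_tree(n_tips: int, seed: int, birth_rate: float = 0.4) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_tips,
        taxon_namespace=taxa, rng=random.Random(seed))
    # the simulator stops exactly at a speciation event, leaving a
    # zero-length cherry that makes the phylogenetic covariance singular;
    # extending every terminal branch keeps the tree ultrametric
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += 0.02 / birth_rate
    return tree


def newick(s: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=s, schema="newick")


@pytest.fixture
def balanced4():
    """Balanced ultrametric 4-tip tree, all unit branches (depth 2)."""
    return newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def two_tip():
    return newick("(A:1.0,B:1.0);")


@pytest.fixture
def small_traits():
    return TraitTable({"A": 0.3, "B": -0.2, "C": 0.1, "D": 0.0})


@pytest.fixture
def rng():
    return np.random.default_rng(0)
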