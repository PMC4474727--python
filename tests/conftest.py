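"""Shared fixtures and independent brute-force oracles.

The oracles work directly on dendropy trees via descendant-leaf-set
classification, independent of the package's edge-index path."""

import numpy as np
import pytest

from pdbarcoder import PhyloTree, simulate_tree, TreeSimConfig

T0_NEWICK = "((A:1.0,B:2.0):3.0,C:4.0);"
TOY_FASTA = ">x1|GenX_alpha\nACGT\n>y1|GenY_beta\nAGGT\n>y2|GenY_beta\nAGGA\n"


@pytest.fixture
def t0():
    return PhyloTree.from_newick(T0_NEWICK)


@pytest.fixture
def toy_fasta():
    return TOY_FASTA


def brute_pd_inclusive(tree: PhyloTree, group) -> float:
    """Sum of lengths over edges whose descendant leaf set meets the group."""
    group = set(group)
    total = 0.0
    for node in tree.dendropy_tree.preorder_node_iter():
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if below & group:
            total += node.edge.length or 0.0
    return total


def brute_pd_exclusive(tree: PhyloTree, group) -> float:
    """Sum of lengths over edges whose descendant leaves all lie in the group."""
    group = set(group)
    total = 0.0
    for node in tree.dendropy_tree.preorder_node_iter():
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if below <= group:
            total += node.edge.length or 0.0
    return total


def random_tree(n_leaves: int, seed: int) -> PhyloTree:
    return simulate_tree(
        TreeSimConfig(n_leaves=n_leaves, mean_branch_length=0.2, seed=seed)
    )


def all_nonempty_subsets(labels):
    labels = sorted(labels)
    n = len(labels)
    for mask in range(1, 2**n):
        yield [labels[i] for i in range(n) if mask >> i & 1]
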