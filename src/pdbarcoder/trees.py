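"""Rooted branch-length trees: Newick I/O and group-restricted pruning.

The :class:`PhyloTree` wrapper keeps a dendropy tree underneath but pins
down the conventions the diversity math relies on:

* edge lengths are non-negative reals (substitutions/site); a missing
  length in the Newick source is read as 0,
* leaf labels are unique strings,
* the total length of a tree is the sum over *all* edges, including any
  length attached to the root,
* pruning to a leaf subset retains exactly the edges that have at least
  one descendant in the subset; chains of degree-2 nodes created by the
  pruning are merged with their lengths summed, so the pruned tree's
  total length equals the sum over retained original edges.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy

__all__ = ["PhyloTree", "NewickError"]


class NewickError(ValueError):
    """Malformed Newick input or violated tree invariants."""


class PhyloTree:
    """A rooted tree with non-negative branch lengths and unique leaf labels."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        """Parse a Newick string.

        Internal node labels (e.g. bootstrap values) are retained but play
        no role in any computation. Missing branch lengths become 0.
        """
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickError(f"malformed Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_newick(fh.read())

    def _validate(self) -> None:
        seen: set[str] = set()
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise NewickError("leaf without a label")
            label = leaf.taxon.label
            if label in seen:
                raise NewickError(f"duplicate leaf label {label!r}")
            seen.add(label)
        for node in self._tree.preorder_node_iter():
            length = node.edge.length
            if length is not None and length < 0:
                raise NewickError(
                    f"negative edge length {length} above "
                    f"{node.taxon.label if node.taxon else 'internal node'}"
                )

    # -- basic properties ---------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def total_length(self) -> float:
        return sum(
            node.edge.length or 0.0 for node in self._tree.preorder_node_iter()
        )

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        return s

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_leaves={self.n_leaves}, total_length={self.total_length:.6g})"

    # -- pruning -------------------------------------------------------

    def check_group(self, group: Iterable[str]) -> frozenset[str]:
        """Validate a leaf group: non-empty and a subset of this tree's leaves."""
        members = frozenset(group)
        if not members:
            raise ValueError("leaf group is empty")
        unknown = members - set(self.leaf_labels)
        if unknown:
            raise ValueError(
                f"leaf group contains labels absent from the tree: {sorted(unknown)}"
            )
        return members

    def prune_to(self, keep: Iterable[str]) -> "PhyloTree":
        """Restrict the tree to the leaves in ``keep``.

        Retains every edge with at least one descendant leaf in ``keep``;
        degree-2 chains are merged with lengths summed and no stem above
        the kept clade is discarded, so ``pruned.total_length`` equals the
        inclusive diversity of ``keep`` on the original tree.
        """
        members = self.check_group(keep)
        taxa = dendropy.TaxonNamespace()
        new_tree = dendropy.Tree(taxon_namespace=taxa)

        def build(node) -> tuple[dendropy.Node, float] | None:
            stem = node.edge.length or 0.0
            if node.is_leaf():
                if node.taxon.label not in members:
                    return None
                fresh = dendropy.Node()
                fresh.taxon = taxa.require_taxon(label=node.taxon.label)
                return fresh, stem
            kept = [r for r in (build(c) for c in node.child_nodes()) if r]
            if not kept:
                return None
            if len(kept) == 1:
                child, child_stem = kept[0]
                return child, child_stem + stem
            fresh = dendropy.Node()
            for child, child_stem in kept:
                child.edge.length = child_stem
                fresh.add_child(child)
            return fresh, stem

        built = build(self._tree.seed_node)
        assert built is not None  # members is non-empty
        top, stem = built
        if top.is_leaf() or stem > 0:
            # preserve the stem (and give single-leaf prunes a root)
            root = dendropy.Node()
            top.edge.length = stem
            root.add_child(top)
        else:
            root = top
        new_tree.seed_node = root
        return PhyloTree(new_tree)

    # -- edge/leaf incidence (used by the diversity module) ------------

    def edge_index(self) -> "EdgeIndex":
        return EdgeIndex(self)


class EdgeIndex:
    """Edge lengths plus, per leaf, the chain of edges on its root path.

    Built once per tree and reused across many subset queries; the
    diversity functions express PD sums as unions of root paths.
    """

    def __init__(self, tree: PhyloTree):
        nodes = list(tree.dendropy_tree.preorder_node_iter())
        self.n_edges = len(nodes)
        self.lengths = [node.edge.length or 0.0 for node in nodes]
        index_of = {id(node): i for i, node in enumerate(nodes)}
        self.leaf_paths: dict[str, list[int]] = {}
        for leaf in tree.dendropy_tree.leaf_node_iter():
            path = []
            node = leaf
            while node is not None:
                path.append(index_of[id(node)])
                node = node.parent_node
            self.leaf_paths[leaf.taxon.label] = path
        # per-edge count of descendant leaves, for analytic rarefaction
        self.n_desc_leaves = [0] * self.n_edges
        for path in self.leaf_paths.values():
            for e in path:
                self.n_desc_leaves[e] += 1

    def members_below(self, members: Sequence[str]) -> list[int]:
        """Per-edge count of members in the edge's descendant leaf set."""
        counts = [0] * self.n_edges
        for label in members:
            for e in self.leaf_paths[label]:
                counts[e] += 1
        return counts
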