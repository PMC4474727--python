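"""Synthetic trees, province annotations and barcode alignments.

These generators produce inputs with known truth so the diversity and
assignment machinery can be validated end to end:

* :func:`simulate_tree` — random rooted binary topologies (uniform
  coalescent-style joins) with i.i.d. exponential branch lengths in
  substitutions/site.
* :func:`assign_provinces` — leaf-to-province annotations either sampled
  independently per leaf ("random", dispersal-assembled provinces) or
  concentrated on a single clade ("clustered", in-situ diversification);
  clustering drives the exclusive/inclusive diversity ratio up because
  the internal edges of a clade are private to its members.
* :func:`simulate_barcodes` — species consensus sequences evolved along a
  simulated species tree under Jukes–Cantor, with individuals radiating
  from their species consensus on a star (the barcode-gap idealization:
  interspecific divergence well above intraspecific).

Everything is driven by a single integer seed per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .barcoding import BarcodeDB, BarcodeRecord
from .diversity import ProvinceMap
from .trees import PhyloTree

__all__ = [
    "TreeSimConfig",
    "BarcodeSimConfig",
    "simulate_tree",
    "assign_provinces",
    "clade_sizes",
    "simulate_barcodes",
    "jc_evolve",
    "jc_expected_p_distance",
]


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class TreeSimConfig:
    n_leaves: int
    mean_branch_length: float = 0.1  # substitutions/site
    seed: int | None = None
    label_prefix: str = "t"

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")
        if self.mean_branch_length <= 0:
            raise ValueError("mean_branch_length must be > 0")


def simulate_tree(config: TreeSimConfig) -> PhyloTree:
    """Random rooted binary tree on ``n_leaves`` labeled tips.

    Topology: repeatedly join two uniformly chosen lineages until one
    remains (every labeled topology reachable).  Each non-root edge gets
    an independent Exponential(mean_branch_length) length; the root
    carries no edge length, so an n-leaf tree has 2n - 2 measured edges.
    """
    rng = np.random.default_rng(config.seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    width = max(3, len(str(config.n_leaves)))
    lineages = []
    for i in range(config.n_leaves):
        node = dendropy.Node()
        node.taxon = taxa.require_taxon(
            label=f"{config.label_prefix}{i + 1:0{width}d}"
        )
        lineages.append(node)
    while len(lineages) > 1:
        i, j = rng.choice(len(lineages), size=2, replace=False)
        a, b = lineages[int(i)], lineages[int(j)]
        parent = dendropy.Node()
        for child in (a, b):
            child.edge.length = float(rng.exponential(config.mean_branch_length))
            parent.add_child(child)
        lineages = [x for x in lineages if x is not a and x is not b]
        lineages.append(parent)
    tree.seed_node = lineages[0]
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# province annotation
# ---------------------------------------------------------------------------

def clade_sizes(tree: PhyloTree) -> dict[int, int]:
    """Histogram {clade size: count} over internal nodes (size >= 2)."""
    sizes: dict[int, int] = {}
    for node in tree.dendropy_tree.preorder_internal_node_iter():
        size = sum(1 for _ in node.leaf_iter())
        sizes[size] = sizes.get(size, 0) + 1
    return sizes


def assign_provinces(
    tree: PhyloTree,
    mode: str,
    params: dict,
    seed: int | None = None,
) -> ProvinceMap:
    """Annotate tree leaves with marine-province memberships.

    ``mode="random"`` — params ``{"province": name, "p": prob}`` for
    independent per-leaf membership, or ``{"province": name, "size": m}``
    for a uniform sample of exactly m leaves (useful for matched-N
    comparisons). Multiple provinces may be given as
    ``{"provinces": {name: p, ...}}``.

    ``mode="clustered"`` — params ``{"province": name, "clade_size": m,
    "noise_p": q}``: the leaves of one uniformly chosen internal node
    with exactly m descendant leaves form the province; each outside leaf
    joins independently with probability q (default 0).

    Every declared province must end up non-empty.
    """
    rng = np.random.default_rng(seed)
    leaves = tree.leaf_labels
    membership: dict[str, set[str]] = {}

    def add(leaf: str, province: str) -> None:
        membership.setdefault(leaf, set()).add(province)

    declared: list[str] = []
    if mode == "random":
        if "provinces" in params:
            spec = {
                name: (cfg if isinstance(cfg, dict) else {"p": float(cfg)})
                for name, cfg in params["provinces"].items()
            }
        else:
            spec = {
                params.get("province", "P1"): {
                    k: v for k, v in params.items() if k in ("p", "size")
                }
            }
        for province, cfg in spec.items():
            declared.append(province)
            if "size" in cfg:
                size = int(cfg["size"])
                if not 1 <= size <= len(leaves):
                    raise ValueError(
                        f"size {size} out of range for {len(leaves)} leaves"
                    )
                for i in rng.choice(len(leaves), size=size, replace=False):
                    add(leaves[int(i)], province)
            elif "p" in cfg:
                p = float(cfg["p"])
                if not 0 <= p <= 1:
                    raise ValueError(f"membership probability {p} outside [0, 1]")
                for leaf in leaves:
                    if rng.random() < p:
                        add(leaf, province)
            else:
                raise ValueError(
                    f"random mode needs 'p' or 'size' for province {province!r}"
                )
    elif mode == "clustered":
        province = params.get("province", "P1")
        declared.append(province)
        size = int(params["clade_size"])
        noise_p = float(params.get("noise_p", 0.0))
        candidates = [
            node
            for node in tree.dendropy_tree.preorder_internal_node_iter()
            if sum(1 for _ in node.leaf_iter()) == size
        ]
        if not candidates:
            raise ValueError(
                f"no clade of size {size}; available sizes: "
                f"{sorted(clade_sizes(tree))}"
            )
        node = candidates[int(rng.integers(len(candidates)))]
        clade = {leaf.taxon.label for leaf in node.leaf_iter()}
        for leaf in clade:
            add(leaf, province)
        if noise_p > 0:
            for leaf in leaves:
                if leaf not in clade and rng.random() < noise_p:
                    add(leaf, province)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    present = set().union(*membership.values()) if membership else set()
    missing = [p for p in declared if p not in present]
    if missing:
        raise ValueError(f"provinces ended up empty: {missing}")
    return ProvinceMap.from_pairs(
        (leaf, prov) for leaf, provs in membership.items() for prov in provs
    )


# ---------------------------------------------------------------------------
# barcodes (Jukes–Cantor)
# ---------------------------------------------------------------------------

@dataclass
class BarcodeSimConfig:
    n_species: int
    seqs_per_species: int | list[int] = 3  # singletons allowed
    alignment_length: int = 658  # the standard COI barcode length
    interspecific: float = 0.05  # expected subs/site on species-tree edges
    intraspecific: float = 0.005  # expected subs/site, consensus -> individual
    seed: int | None = None

    counts: list[int] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if self.interspecific < 0 or self.intraspecific < 0:
            raise ValueError("divergences must be >= 0")
        if isinstance(self.seqs_per_species, int):
            if self.seqs_per_species < 1:
                raise ValueError("seqs_per_species must be >= 1")
            self.counts = [self.seqs_per_species] * self.n_species
        else:
            self.counts = [int(c) for c in self.seqs_per_species]
            if len(self.counts) != self.n_species:
                raise ValueError("seqs_per_species list must have n_species entries")
            if any(c < 1 for c in self.counts):
                raise ValueError("every species needs >= 1 sequence")


def jc_evolve(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an encoded (0..3) sequence for ``t`` expected subs/site (JC69).

    Per site the probability of ending in a *different* base is
    (3/4)(1 - exp(-4t/3)); a substituted site picks uniformly among the
    three other bases.
    """
    if t == 0:
        return seq.copy()
    p_diff = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    out = seq.copy()
    hit = rng.random(seq.size) < p_diff
    n_hit = int(hit.sum())
    if n_hit:
        # uniform over the 3 non-current bases via an offset 1..3 mod 4
        out[hit] = (out[hit] + rng.integers(1, 4, size=n_hit)) % 4
    return out


def jc_expected_p_distance(t: float) -> float:
    """Expected p-distance between sequence ends separated by ``t`` subs/site."""
    return 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))


def simulate_barcodes(config: BarcodeSimConfig) -> tuple[BarcodeDB, dict[str, str]]:
    """Simulate an aligned barcode database with known species truth.

    Returns ``(db, truth)`` where ``truth`` maps seq_id -> true species.
    Species are named "GenusNNN speciesNNN" (one genus per species unless
    callers relabel), consensus sequences evolve along a random species
    tree whose edges have mean length ``interspecific``, and individuals
    evolve from their consensus by ``intraspecific``.
    """
    rng = np.random.default_rng(config.seed)
    bases = np.array(list("ACGT"))
    root = rng.integers(0, 4, size=config.alignment_length).astype(np.uint8)

    width = max(3, len(str(config.n_species)))
    names = [
        f"Genus{i + 1:0{width}d} species{i + 1:0{width}d}"
        for i in range(config.n_species)
    ]
    if config.n_species == 1:
        consensi = {names[0]: jc_evolve(root, config.interspecific, rng)}
    else:
        stree = simulate_tree(
            TreeSimConfig(
                n_leaves=config.n_species,
                mean_branch_length=max(config.interspecific, 1e-12),
                seed=int(rng.integers(2**31)),
                label_prefix="sp",
            )
        )
        consensi = {}
        leaf_names = {}
        for i, label in enumerate(sorted(stree.leaf_labels)):
            leaf_names[label] = names[i]
        seqs_at: dict[int, np.ndarray] = {}

        for node in stree.dendropy_tree.preorder_node_iter():
            if node.parent_node is None:
                seqs_at[id(node)] = root
            else:
                t = node.edge.length or 0.0
                # degenerate interspecific==0 collapses all consensi onto the root
                if config.interspecific == 0:
                    t = 0.0
                seqs_at[id(node)] = jc_evolve(seqs_at[id(node.parent_node)], t, rng)
            if node.is_leaf():
                consensi[leaf_names[node.taxon.label]] = seqs_at[id(node)]

    records = []
    truth: dict[str, str] = {}
    counter = 0
    for species, count in zip(names, config.counts):
        cons = consensi[species]
        for _ in range(count):
            counter += 1
            seq_id = f"s{counter:04d}"
            indiv = jc_evolve(cons, config.intraspecific, rng)
            records.append(
                BarcodeRecord(
                    seq_id=seq_id,
                    species=species,
                    seq="".join(bases[indiv]),
                )
            )
            truth[seq_id] = species
    return BarcodeDB(records), truth
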