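"""Inclusive/exclusive phylogenetic diversity and its rarefaction.

Definitions (edge-based, rooted):

* ``PD_I(G)`` — inclusive phylogenetic diversity — is the summed length of
  every edge with at least one descendant leaf in the group ``G``;
  equivalently the total length of the tree obtained by trimming all
  leaves outside ``G``.  It measures the total evolutionary heritage of
  the group, root included.
* ``PD_E(G)`` — exclusive phylogenetic diversity — is the summed length of
  the edges whose descendant leaves all belong to ``G``; equivalently the
  total tree length minus ``PD_I`` of the complement group.  It captures
  change that happened only on lineages private to the group, a proxy for
  in-situ evolution within a region.

These two readings are exactly complementary:
``PD_E(G) + PD_I(L \\ G) = total_length`` for every group with a
non-empty complement.  An unrooted "minimal spanning path" variant of
``PD_I`` (which drops the root path above the group's MRCA) is available
via ``convention="unrooted"``.

Rarefaction estimates ``E[PD_I]`` at standardized sample sizes
``k = 1..N`` by subsampling leaves uniformly without replacement, so
provinces with unequal sampling effort can be compared.  Subsamples are
nested (each pseudoreplicate draws one random leaf permutation and scores
its prefixes), which keeps the estimated mean curve monotone in ``k``
while leaving every per-``k`` marginal an exact uniform draw of size
``k``.  An exact mode computes ``E[PD_I,k]`` analytically from the
hypergeometric probability that an edge's descendant members are missed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .trees import PhyloTree

__all__ = [
    "ProvinceMap",
    "PDResult",
    "RarefactionCurve",
    "normalize_species_name",
    "read_province_table",
    "pd_inclusive",
    "pd_exclusive",
    "pd_report",
    "rarefy_pd",
]


# ---------------------------------------------------------------------------
# province annotations
# ---------------------------------------------------------------------------

def normalize_species_name(name: str) -> str:
    """Normalization key for matching leaf labels to species names.

    Underscores become spaces, whitespace collapses, comparison is
    case-insensitive on the "Genus species" prefix (first two tokens), so
    ``Tedania_oxeata_ZMA123`` matches ``Tedania oxeata``.
    """
    tokens = re.sub(r"\s+", " ", name.replace("_", " ")).strip().split(" ")
    return " ".join(tokens[:2]).casefold()


@dataclass
class ProvinceMap:
    """Species -> set-of-marine-province annotations.

    ``entries`` maps *normalized* species keys to province sets;
    ``provinces`` is the controlled vocabulary. Species absent from
    ``entries`` are unannotated.
    """

    entries: dict[str, set[str]]
    provinces: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.provinces:
            self.provinces = set().union(*self.entries.values()) if self.entries else set()
        for species, provs in self.entries.items():
            if not provs:
                raise ValueError(f"species {species!r} maps to no province")
            bad = provs - self.provinces
            if bad:
                raise ValueError(
                    f"species {species!r} annotated with unknown provinces {sorted(bad)}"
                )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ProvinceMap":
        entries: dict[str, set[str]] = {}
        for species, province in pairs:
            entries.setdefault(normalize_species_name(species), set()).add(province)
        return cls(entries=entries)

    def provinces_of(self, name: str) -> set[str]:
        return self.entries.get(normalize_species_name(name), set())

    def match_leaves(self, tree: PhyloTree) -> tuple[dict[str, set[str]], list[str]]:
        """Map each leaf label to its provinces; also return unannotated labels."""
        matched: dict[str, set[str]] = {}
        unmatched: list[str] = []
        for label in tree.leaf_labels:
            provs = self.provinces_of(label)
            if provs:
                matched[label] = provs
            else:
                unmatched.append(label)
        return matched, unmatched


def read_province_table(source) -> ProvinceMap:
    """Read a TSV with header ``species<TAB>province``, one row per pair."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"species", "province"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"province table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    df = df.dropna(subset=["species", "province"])
    return ProvinceMap.from_pairs(zip(df["species"], df["province"]))


def write_province_table(pmap_or_pairs, path) -> None:
    if isinstance(pmap_or_pairs, ProvinceMap):
        rows = [
            (sp, prov)
            for sp, provs in sorted(pmap_or_pairs.entries.items())
            for prov in sorted(provs)
        ]
    else:
        rows = list(pmap_or_pairs)
    pd.DataFrame(rows, columns=["species", "province"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# PD proper
# ---------------------------------------------------------------------------

def _edge_member_counts(tree: PhyloTree, group: Iterable[str]):
    members = tree.check_group(group)
    index = tree.edge_index()
    counts = index.members_below(sorted(members))
    return members, index, counts


def pd_inclusive(
    tree: PhyloTree, group: Iterable[str], convention: str = "rooted"
) -> float:
    """Summed length of edges with >= 1 descendant leaf in ``group``.

    ``convention="unrooted"`` instead sums the minimal subtree spanning
    the group (the rooted sum minus the path from the root down to the
    group's MRCA).
    """
    members, index, counts = _edge_member_counts(tree, group)
    if convention == "rooted":
        return sum(l for l, c in zip(index.lengths, counts) if c > 0)
    if convention == "unrooted":
        # minimal spanning subtree: drop the root-to-MRCA chain, i.e. every
        # edge with *all* n members below it (0 for a single leaf)
        n = len(members)
        return sum(l for l, c in zip(index.lengths, counts) if 0 < c < n)
    raise ValueError(f"unknown PD convention {convention!r}")


def pd_exclusive(tree: PhyloTree, group: Iterable[str]) -> float:
    """Summed length of edges whose descendant leaves are all in ``group``.

    Equals ``total_length - PD_I(complement)``; for the full leaf set it
    is the whole tree length.
    """
    members, index, counts = _edge_member_counts(tree, group)
    return sum(
        l
        for l, c, n in zip(index.lengths, counts, index.n_desc_leaves)
        if c == n
    )


@dataclass
class PDResult:
    """Province-level diversity summary: PD_I, PD_E, their ratio, group size N."""

    province: str
    pd_inclusive: float
    pd_exclusive: float
    ratio: float
    n: int

    def as_dict(self) -> dict:
        return {
            "pd_i": self.pd_inclusive,
            "pd_e": self.pd_exclusive,
            "ratio": self.ratio,
            "n": self.n,
        }


def pd_report(
    tree: PhyloTree,
    province_map: ProvinceMap,
    province: str,
    retain_unannotated: bool = False,
) -> PDResult:
    """PD_I, PD_E and PD_E/PD_I for the leaves annotated to ``province``.

    Leaves that match no species in the annotation table are by default
    trimmed from the tree before any computation (so they inflate neither
    the PD_E baseline nor the total length); ``retain_unannotated=True``
    keeps them, in which case they count toward the total length that
    PD_E is measured against.
    """
    matched, unmatched = province_map.match_leaves(tree)
    if not matched:
        raise ValueError(
            f"no tree leaf matched any annotated species; unmatched leaves: {unmatched}"
        )
    work = tree if retain_unannotated or not unmatched else tree.prune_to(matched)
    group = [lab for lab, provs in matched.items() if province in provs]
    if not group:
        raise ValueError(
            f"province {province!r} matched no leaf; annotated leaves: {sorted(matched)}"
        )
    pdi = pd_inclusive(work, group)
    pde = pd_exclusive(work, group)
    ratio = pde / pdi if pdi > 0 else 0.0
    return PDResult(
        province=province,
        pd_inclusive=pdi,
        pd_exclusive=pde,
        ratio=ratio,
        n=len(group),
    )


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

@dataclass
class RarefactionCurve:
    """Per-k subsampled PD_I summaries for k = 1..N."""

    k: np.ndarray
    mean_pd: np.ndarray
    sd_pd: np.ndarray
    q05: np.ndarray
    q95: np.ndarray
    n_reps: int
    seed: int | None
    method: str = "monte-carlo"

    def to_frame(self, province: str = "") -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "k": self.k,
                "mean_pd": self.mean_pd,
                "sd_pd": self.sd_pd,
                "q05": self.q05,
                "q95": self.q95,
            }
        )
        df.insert(0, "province", province)
        df["n_reps"] = self.n_reps
        df["seed"] = self.seed
        return df


def rarefy_pd(
    tree: PhyloTree,
    group: Iterable[str],
    n_reps: int = 1000,
    seed: int | None = None,
    method: str = "monte-carlo",
) -> RarefactionCurve:
    """Rarefaction curve of PD_I over subsample sizes k = 1..N.

    ``method="monte-carlo"`` (default) scores ``n_reps`` nested uniform
    subsamples per k.  ``method="exact"`` enumerates every C(N, k) subset
    when that count is small (<= 200000 per k) and otherwise falls back to
    the closed-form mean
    ``E[PD_I,k] = sum_e len_e * (1 - C(N - m_e, k) / C(N, k))``
    with the per-k standard deviation reported as NaN.
    """
    members = sorted(tree.check_group(group))
    n = len(members)
    index = tree.edge_index()
    lengths = np.asarray(index.lengths)
    # per-leaf root paths as index arrays for incremental prefix scoring
    paths = [np.asarray(index.leaf_paths[m]) for m in members]
    if method == "exact":
        return _rarefy_exact(lengths, paths, n, index.n_edges)
    if method != "monte-carlo":
        raise ValueError(f"unknown rarefaction method {method!r}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    pd_by_rep = np.empty((n_reps, n))
    for rep in range(n_reps):
        order = rng.permutation(n)
        seen = np.zeros(index.n_edges, dtype=bool)
        running = 0.0
        for pos, leaf_i in enumerate(order):
            path = paths[leaf_i]
            fresh = path[~seen[path]]
            running += float(lengths[fresh].sum())
            seen[fresh] = True
            pd_by_rep[rep, pos] = running
    # at k = N every rep covers the same edge set; pin the value so the
    # terminal point equals PD_I with zero variance regardless of the
    # floating-point accumulation order
    touched = np.zeros(index.n_edges, dtype=bool)
    for path in paths:
        touched[path] = True
    full_pd = float(lengths[touched].sum())
    pd_by_rep[:, -1] = full_pd
    mean = pd_by_rep.mean(axis=0)
    sd = pd_by_rep.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(n)
    mean[-1], sd[-1] = full_pd, 0.0  # constant column, free of reduction rounding
    q05 = np.quantile(pd_by_rep, 0.05, axis=0)
    q95 = np.quantile(pd_by_rep, 0.95, axis=0)
    return RarefactionCurve(
        k=np.arange(1, n + 1),
        mean_pd=mean,
        sd_pd=sd,
        q05=q05,
        q95=q95,
        n_reps=n_reps,
        seed=seed,
    )


_ENUM_CAP = 200_000


def _rarefy_exact(lengths, paths, n, n_edges) -> RarefactionCurve:
    """Closed-form rarefaction mean, with sd/quantiles by full enumeration
    wherever C(N, k) <= the enumeration cap (NaN beyond it)."""
    from itertools import combinations

    ks = np.arange(1, n + 1)
    means = np.empty(n)
    sds = np.full(n, np.nan)
    q05 = np.full(n, np.nan)
    q95 = np.full(n, np.nan)
    # member count below each edge, restricted to the group
    member_counts = np.zeros(n_edges, dtype=int)
    inc = np.zeros((n, n_edges), dtype=bool)
    for i, path in enumerate(paths):
        inc[i, path] = True
        member_counts[path] += 1
    touched = member_counts > 0
    m = member_counts[touched]
    l_touched = lengths[touched]
    inc_touched = inc[:, touched]
    for i, k in enumerate(ks):
        total = comb(n, int(k))
        # an edge enters PD_I,k unless all k draws miss its m_e members
        missed = np.array([comb(n - int(me), int(k)) for me in m]) / total
        means[i] = float((l_touched * (1.0 - missed)).sum())
        if total <= _ENUM_CAP:
            vals = np.fromiter(
                (
                    float(l_touched[inc_touched[list(subset)].any(axis=0)].sum())
                    for subset in combinations(range(n), int(k))
                ),
                dtype=float,
                count=total,
            )
            sds[i] = vals.std(ddof=0)
            q05[i] = np.quantile(vals, 0.05)
            q95[i] = np.quantile(vals, 0.95)
    return RarefactionCurve(
        k=ks,
        mean_pd=means,
        sd_pd=sds,
        q05=q05,
        q95=q95,
        n_reps=0,
        seed=None,
        method="exact",
    )


def enumerate_rarefaction(tree: PhyloTree, group: Iterable[str]) -> pd.DataFrame:
    """Exhaustively enumerate PD_I over every subset size (small N only).

    Returns a frame with columns ``k, mean_pd, sd_pd`` computed over all
    C(N, k) subsets; used as the reference that Monte-Carlo estimates are
    checked against.
    """
    from itertools import combinations

    members = sorted(tree.check_group(group))
    n = len(members)
    index = tree.edge_index()
    lengths = np.asarray(index.lengths)
    # leaf-by-edge incidence
    inc = np.zeros((n, index.n_edges), dtype=bool)
    for i, memb in enumerate(members):
        inc[i, index.leaf_paths[memb]] = True
    rows = []
    for k in range(1, n + 1):
        vals = []
        for subset in combinations(range(n), k):
            vals.append(float(lengths[inc[list(subset)].any(axis=0)].sum()))
        vals = np.asarray(vals)
        rows.append((k, vals.mean(), vals.std(ddof=0)))
    return pd.DataFrame(rows, columns=["k", "mean_pd", "sd_pd"])
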