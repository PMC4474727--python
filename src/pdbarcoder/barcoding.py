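"""Minimum-risk barcode species assignment on segregating sites.

A query sequence S is assigned against a database of aligned, species-
labeled barcodes (typically the ~658 bp COI fragment) in three steps:

1. *Segregating sites.* Only alignment columns where the database shows
   at least two distinct unambiguous nucleotides carry identification
   signal; all other columns are ignored.

2. *Posterior.* Per candidate species k, a per-site categorical model
   with Laplace pseudocount alpha gives

       P(k | S)  proportional to  prod_j (c_{k,j,S_j} + alpha) / (n_{k,j} + 4 alpha)

   over segregating sites j where the query base is unambiguous, with a
   uniform prior over species (computed in log space).  ``c`` counts the
   query's base among species k's sequences at site j, ``n`` the
   unambiguous bases of species k there.

3. *Minimum risk.* The loss of calling species i when the truth is k is
   the p-distance between the query and the consensus of i (zero when
   i = k), so the expected loss is

       Risk(i) = d(S, consensus_i) * (1 - P(i | S))

   and the call is the risk-minimizing species.  A variant loss using
   consensus-to-consensus distances, Risk(i) = sum_k P(k|S) d(cons_i,
   cons_k), is available via ``loss="consensus"``.

Accuracy is estimated by leave-one-out cross-validation: each sequence is
queried against the database rebuilt without it.  A trial is correct if
the minimum-risk species matches the truth, or — for species represented
by a single sequence, which cannot match themselves — if the call is a
congener of the true species.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "BarcodeDB",
    "SpeciesProfile",
    "AssignmentResult",
    "LoocvReport",
    "read_barcode_fasta",
    "segregating_sites",
    "species_profiles",
    "posterior",
    "p_distance",
    "assignment_risk",
    "standardize_risks",
    "loocv",
]

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}  # anything else -> ambiguous


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, gaps / N / IUPAC ambiguity codes -> 255."""
    arr = np.full(len(seq), 255, dtype=np.uint8)
    for i, ch in enumerate(seq.upper()):
        arr[i] = _BASE_CODE.get(ch, 255)
    return arr


# ---------------------------------------------------------------------------
# database container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BarcodeRecord:
    seq_id: str
    species: str
    seq: str

    @property
    def genus(self) -> str:
        return self.species.split()[0]


class BarcodeDB:
    """Aligned, species-labeled candidate sequences.

    All sequences share one alignment length; sequence ids are unique;
    species names are binomials ("Genus species", genus = first token).
    """

    def __init__(self, records: Sequence[BarcodeRecord]):
        if not records:
            raise ValueError("barcode database is empty")
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            bad = [r.seq_id for r in records if len(r.seq) != len(records[0].seq)]
            raise ValueError(
                f"unequal alignment length (offending records include {bad[:5]})"
            )
        ids = [r.seq_id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        for r in records:
            if not r.species.strip():
                raise ValueError(f"record {r.seq_id!r} has no species name")
        self.records: tuple[BarcodeRecord, ...] = tuple(records)
        self.alignment_length: int = len(records[0].seq)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species_names(self) -> list[str]:
        return sorted({r.species for r in self.records})

    def by_species(self) -> dict[str, list[BarcodeRecord]]:
        out: dict[str, list[BarcodeRecord]] = {}
        for r in self.records:
            out.setdefault(r.species, []).append(r)
        return out

    def without(self, seq_id: str) -> "BarcodeDB":
        kept = [r for r in self.records if r.seq_id != seq_id]
        if len(kept) == len(self.records):
            raise KeyError(f"no record with id {seq_id!r}")
        return BarcodeDB(kept)

    def encoded(self) -> np.ndarray:
        return np.stack([_encode(r.seq) for r in self.records])

    def to_fasta(self, path=None) -> str | None:
        recs = [
            SeqRecord(
                Seq(r.seq),
                id=f"{r.seq_id}|{r.species.replace(' ', '_')}",
                description="",
            )
            for r in self.records
        ]
        if path is None:
            buf = io.StringIO()
            SeqIO.write(recs, buf, "fasta")
            return buf.getvalue()
        SeqIO.write(recs, str(path), "fasta")
        return None


def read_barcode_fasta(source) -> BarcodeDB:
    """Read an aligned FASTA whose headers follow ``>seq_id|Genus_species``."""
    if isinstance(source, str) and "\n" in source:
        handle = io.StringIO(source)
    else:
        handle = open(source, "r", encoding="utf-8")
    try:
        records = []
        for rec in SeqIO.parse(handle, "fasta"):
            if "|" not in rec.id:
                raise ValueError(
                    f"record {rec.id!r}: header must be 'seq_id|Genus_species'"
                )
            seq_id, _, species_raw = rec.id.partition("|")
            species = " ".join(species_raw.replace("_", " ").split())
            if not seq_id or not species:
                raise ValueError(
                    f"record {rec.id!r}: missing sequence id or species field"
                )
            records.append(BarcodeRecord(seq_id=seq_id, species=species, seq=str(rec.seq)))
    finally:
        handle.close()
    return BarcodeDB(records)


# ---------------------------------------------------------------------------
# segregating sites and per-species profiles
# ---------------------------------------------------------------------------

def segregating_sites(db: BarcodeDB) -> list[int]:
    """0-based columns with >= 2 distinct unambiguous bases across the database."""
    enc = db.encoded()
    sites = []
    for j in range(db.alignment_length):
        col = enc[:, j]
        if len(np.unique(col[col < 4])) >= 2:
            sites.append(j)
    return sites


@dataclass
class SpeciesProfile:
    """Per-species base counts and majority-rule consensus."""

    species: str
    n_seqs: int
    counts: np.ndarray  # (alignment_length, 4) unambiguous-base counts
    consensus: str

    @property
    def genus(self) -> str:
        return self.species.split()[0]


def species_profiles(db: BarcodeDB) -> list[SpeciesProfile]:
    """Profiles sorted by species name.

    Consensus is majority rule over unambiguous bases; ties break to the
    alphabetically first base (A < C < G < T); all-gap/ambiguous columns
    yield a gap.
    """
    profiles = []
    for species, recs in sorted(db.by_species().items()):
        enc = np.stack([_encode(r.seq) for r in recs])
        counts = np.zeros((db.alignment_length, 4), dtype=np.int64)
        for b in range(4):
            counts[:, b] = (enc == b).sum(axis=0)
        best = counts.argmax(axis=1)  # argmax takes the first max: A<C<G<T
        cons = np.where(
            counts.sum(axis=1) > 0,
            np.array(list(_BASES))[best],
            "-",
        )
        profiles.append(
            SpeciesProfile(
                species=species,
                n_seqs=len(recs),
                counts=counts,
                consensus="".join(cons),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# posterior, distance, risk
# ---------------------------------------------------------------------------

def posterior(
    query: str,
    profiles: Sequence[SpeciesProfile],
    sites: Sequence[int],
    alpha: float = 1.0,
) -> np.ndarray:
    """P(species | query) over ``profiles``, uniform prior, log-space.

    Sites where the query base is a gap or ambiguity code are skipped. A
    query with no usable segregating site gets the uniform posterior (with
    a warning).
    """
    q = _encode(query)
    usable = [j for j in sites if q[j] < 4]
    if not usable:
        warnings.warn(
            "query has no unambiguous base at any segregating site; "
            "posterior is uniform"
        )
        return np.full(len(profiles), 1.0 / len(profiles))
    logl = np.zeros(len(profiles))
    for i, prof in enumerate(profiles):
        c = prof.counts[usable, q[usable]]
        n = prof.counts[usable].sum(axis=1)
        logl[i] = np.log((c + alpha) / (n + 4.0 * alpha)).sum()
    logl -= logl.max()
    w = np.exp(logl)
    return w / w.sum()


def p_distance(a: str, b: str) -> float:
    """Uncorrected p-distance over sites where both bases are unambiguous.

    With no shared unambiguous site the distance is undefined; 1.0 is
    returned with a warning (maximally distant).
    """
    ea, eb = _encode(a), _encode(b)
    both = (ea < 4) & (eb < 4)
    n = int(both.sum())
    if n == 0:
        warnings.warn("no shared unambiguous sites; p-distance set to 1.0")
        return 1.0
    return float((ea[both] != eb[both]).sum()) / n


@dataclass
class AssignmentResult:
    """Per-candidate posteriors, distances and risks for one query."""

    query_id: str
    species: list[str]
    posteriors: np.ndarray
    distances: np.ndarray  # d(query, consensus_i)
    risks: np.ndarray
    min_risk_species: str
    tied_species: list[str] = field(default_factory=list)
    ambiguous: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "query_id": self.query_id,
                "candidate_species": self.species,
                "posterior": self.posteriors,
                "p_distance": self.distances,
                "risk": self.risks,
            }
        )


_RISK_TIE_TOL = 1e-12


def assignment_risk(
    query: str,
    db: BarcodeDB,
    query_id: str = "query",
    alpha: float = 1.0,
    loss: str = "query-consensus",
) -> AssignmentResult:
    """Minimum-risk assignment of ``query`` against ``db``.

    Default loss: L(i, i) = 0 and L(i, k) = d(query, consensus_i) for
    k != i, giving Risk(i) = d(query, consensus_i) * (1 - P(i | query)).
    ``loss="consensus"`` uses L(i, k) = d(consensus_i, consensus_k)
    instead.  Risk ties (within 1e-12) are reported; the call is the
    alphabetically first tied species, flagged ambiguous.
    """
    profiles = species_profiles(db)
    if len(profiles) < 2:
        raise ValueError("minimum-risk assignment needs at least 2 candidate species")
    if len(query) != db.alignment_length:
        raise ValueError(
            f"query length {len(query)} != alignment length {db.alignment_length}"
        )
    sites = segregating_sites(db)
    post = posterior(query, profiles, sites, alpha=alpha)
    dists = np.array([p_distance(query, p.consensus) for p in profiles])
    if loss == "query-consensus":
        risks = dists * (1.0 - post)
    elif loss == "consensus":
        cc = np.array(
            [
                [p_distance(pi.consensus, pk.consensus) for pk in profiles]
                for pi in profiles
            ]
        )
        risks = cc @ post
    else:
        raise ValueError(f"unknown loss {loss!r}")
    names = [p.species for p in profiles]
    best = float(risks.min())
    tied = [s for s, r in zip(names, risks) if r <= best + _RISK_TIE_TOL]
    return AssignmentResult(
        query_id=query_id,
        species=names,
        posteriors=post,
        distances=dists,
        risks=risks,
        min_risk_species=tied[0],
        tied_species=tied,
        ambiguous=len(tied) > 1,
    )


def standardize_risks(row: Sequence[float], method: str = "printed") -> np.ndarray:
    """Range-standardize one trial's risks.

    ``method="printed"`` applies (R - min) / (max + min); note the
    max maps below 1 whenever min > 0.  ``method="range"`` uses the
    conventional (R - min) / (max - min).  A constant row (degenerate
    denominator) standardizes to all zeros.
    """
    r = np.asarray(row, dtype=float)
    if r.size == 0:
        raise ValueError("empty risk row")
    lo, hi = float(r.min()), float(r.max())
    denom = hi + lo if method == "printed" else hi - lo
    if method not in ("printed", "range"):
        raise ValueError(f"unknown standardization {method!r}")
    if denom == 0:
        return np.zeros_like(r)
    return (r - lo) / denom


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class LoocvReport:
    """Per-trial calls plus sequence- and species-level accuracies."""

    calls: pd.DataFrame
    seq_accuracy: float
    species_accuracy: float
    n_species: int
    n_seqs: int
    n_singletons: int
    risk_matrix_raw: pd.DataFrame
    risk_matrix_std: pd.DataFrame

    def summary(self) -> dict:
        return {
            "n_species": self.n_species,
            "n_seqs": self.n_seqs,
            "seq_accuracy": self.seq_accuracy,
            "species_accuracy": self.species_accuracy,
            "n_singletons": self.n_singletons,
        }


def loocv(
    db: BarcodeDB,
    alpha: float = 1.0,
    loss: str = "query-consensus",
    standardization: str = "printed",
) -> LoocvReport:
    """Leave-one-out cross-validation of minimum-risk assignment.

    Each sequence is queried against the database with that sequence
    removed; segregating sites and species profiles are rebuilt per
    trial.  A trial is correct if the call matches the true species or,
    for singletons (species with exactly one sequence), if the call
    matches the true genus.  Species-level accuracy requires a strict
    majority of a species' trials to be correct.  Standardization of each
    trial's risk row uses the given method; the reported matrices average
    trials by true query species.
    """
    if len(db.species_names) < 2:
        raise ValueError("LOOCV needs a database with at least 2 species")
    counts = {sp: len(recs) for sp, recs in db.by_species().items()}
    rows = []
    raw_rows: list[pd.Series] = []
    std_rows: list[pd.Series] = []
    for rec in db.records:
        rest = db.without(rec.seq_id)
        if len(rest.species_names) < 2:
            raise ValueError(
                "a leave-one-out trial left fewer than 2 candidate species"
            )
        res = assignment_risk(
            rec.seq, rest, query_id=rec.seq_id, alpha=alpha, loss=loss
        )
        singleton = counts[rec.species] == 1
        call = res.min_risk_species
        correct = call == rec.species or (
            singleton and call.split()[0] == rec.genus
        )
        rows.append(
            {
                "seq_id": rec.seq_id,
                "true_species": rec.species,
                "called_species": call,
                "correct": bool(correct),
                "singleton": singleton,
                "ambiguous": res.ambiguous,
                "min_risk": float(res.risks.min()),
            }
        )
        raw_rows.append(
            pd.Series(res.risks, index=res.species, name=rec.species)
        )
        std_rows.append(
            pd.Series(
                standardize_risks(res.risks, method=standardization),
                index=res.species,
                name=rec.species,
            )
        )
    calls = pd.DataFrame(rows)
    seq_acc = float(calls["correct"].mean())
    by_sp = calls.groupby("true_species")["correct"]
    species_correct = by_sp.apply(lambda c: c.sum() * 2 > len(c))
    species_acc = float(species_correct.mean())
    raw = pd.DataFrame(raw_rows).groupby(level=0).mean().sort_index()
    std = pd.DataFrame(std_rows).groupby(level=0).mean().sort_index()
    raw = raw[sorted(raw.columns)]
    std = std[sorted(std.columns)]
    raw.index.name = std.index.name = "query_species"
    return LoocvReport(
        calls=calls,
        seq_accuracy=seq_acc,
        species_accuracy=species_acc,
        n_species=len(counts),
        n_seqs=len(db),
        n_singletons=sum(1 for c in counts.values() if c == 1),
        risk_matrix_raw=raw,
        risk_matrix_std=std,
    )
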