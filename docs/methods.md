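# Methods

## Phylogenetic diversity partitioning

All diversity statistics are edge sums on a rooted tree with non-negative
branch lengths (substitutions/site). For a leaf group *G* on tree *T*
with leaf set *L*:

* PD_I(G) = Σ length(e) over edges *e* with at least one descendant leaf
  in *G*. This equals the total length of the tree obtained by trimming
  every leaf outside *G* while preserving the lengths of retained edges
  (merged degree-2 chains sum their lengths; the stem above the group's
  most recent common ancestor is kept).
* PD_E(G) = Σ length(e) over edges whose descendant leaves all lie in
  *G*, which equals total_length(T) − PD_I(L∖G).

The rooted, edge-based convention was chosen because it is the only one
under which the trim-and-subtract identity
PD_E(G) + PD_I(L∖G) = total_length holds exactly; an unrooted variant
(minimal spanning subtree, dropping the root-to-MRCA chain) is available
via `convention="unrooted"` for users who prefer the path-length reading.
Both PD functions are validated against brute-force edge classification
(descendant-leaf sets computed independently per edge) on random trees,
and rooted PD_I is cross-checked against `picante::pd(include.root=TRUE)`
in R.

**Annotations.** Species→province tables are TSV (`species`, `province`,
one row per pair). Leaf labels match annotation keys after normalizing
underscores to spaces, collapsing whitespace, and comparing the
case-folded "Genus species" prefix, so museum-voucher suffixes on tip
labels do not break matching. Unmatched leaves are reported, never
silently dropped. Leaves matching no annotated species are by default
trimmed before any PD computation — the convention appropriate when
unannotated tips are backbone taxa of unknown provenance — so the PD_E
baseline is the annotated subtree's length. `retain_unannotated=True`
keeps them, making the full tree the baseline; with partial annotation
the two conventions give different PD_E (only the second counts edges
shared with unannotated tips as non-private).

**Rarefaction.** For group size *N*, the curve reports E[PD_I,k] for
k = 1..N. The Monte-Carlo estimator draws `n_reps` (default 1000) random
leaf permutations and scores each prefix incrementally, so one
permutation yields all k at O(total path length) cost. Prefixes of a
uniform permutation are exact uniform without-replacement samples, and
nesting makes each replicate's trajectory — hence the estimated mean
curve — monotone in k by construction rather than only in expectation.
The k = N point is pinned to PD_I with zero variance (every subsample is
the full group). The exact mode computes
E[PD_I,k] = Σ_e length(e)·(1 − C(N−m_e, k)/C(N, k)), with m_e the
group members below edge *e* (the hypergeometric probability that all k
draws miss the edge), and adds sd/quantiles by exhaustive enumeration
whenever C(N,k) ≤ 200 000. Monte-Carlo means are tested to lie within
3 standard errors of full enumeration for N ≤ 10 at 5000 replicates.

## Segregating-sites minimum-risk assignment

The candidate database is an aligned FASTA (`>seq_id|Genus_species`).
Columns with ≥ 2 distinct unambiguous bases (A/C/G/T; gaps, N and IUPAC
codes ignored) across the whole database are the segregating sites; only
they enter the likelihood, since a column identical across all candidates
cannot discriminate among them under shared site-wise frequencies.

Per species *k* and site *j*, c_{kjb} counts unambiguous base *b* among
the species' sequences and n_{kj} their total. With a uniform prior,

    P(k | S) ∝ Π_j (c_{k,j,S_j} + α) / (n_{k,j} + 4α),    α = 1,

over segregating sites where the query base is unambiguous, evaluated in
log space and normalized. A query with no usable site yields the uniform
posterior with a warning. The per-species consensus is majority rule with
ties broken to the alphabetically first base (A<C<G<T), gap where a
column has no unambiguous base.

The loss of calling species *i* is the query-to-consensus p-distance
(computed over sites where both sequences are unambiguous; distance 1
with a warning when no site is shared), zero when the call is correct, so

    Risk(i) = d(S, cons_i) · (1 − P(i | S)).

The call is the argmin; ties within 1e-12 are reported and the
alphabetically first species is returned flagged ambiguous. An
alternative loss using consensus-to-consensus distances,
Risk(i) = Σ_k P(k|S)·d(cons_i, cons_k), is available (`loss="consensus"`).

**LOOCV.** Each sequence is queried against the database with itself
removed; segregating sites and profiles are rebuilt per trial. A trial is
correct if the call equals the true species, or — when the true species
had a single sequence, so it is absent from the candidates — if the call
is a congener. Sequence-level accuracy is the fraction of correct trials;
species-level accuracy counts a species correct when a strict majority of
its trials are (a singleton's one trial decides it). Each trial's risk
row is range standardized as R^s = (R − min R)/(max R + min R); this
form (note the "+" in the denominator, which maps the maximum below 1
whenever min R > 0) is the convention adopted throughout, with the
ordinary (max − min) range form available via `standardization="range"`.
Reported risk matrices average trials by true query species, rows and
columns sorted by name.

**A structural caveat on LOOCV with small, equal samples.** The Laplace
predictive gives a species with n sequences per-site factor
(n+1)/(n+4) even at sites where the query matches every candidate
unanimously. In leave-one-out, the query's own species always competes
with n−1 sequences against the others' n, so every non-discriminating
segregating site contributes a small log-bias toward the competitors —
log[(4/7)/(3/6)] ≈ 0.13 nats at 3-vs-2. When most columns segregate
database-wide (high divergence, many species), overcoming the accumulated
bias requires the query's species to be closer than the competitors by a
margin that grows with alignment length: at 658 bp and 3 sequences per
species the break-even consensus distance is near 0.1 substitutions/site.
Classification of well-separated species can therefore still fail at
moderate divergence (~0.05) under these sample sizes; accuracy rises
steeply with more sequences per species or higher divergence. This is a
property of the model, reproduced faithfully rather than patched, and it
is why the parameter-recovery sweep reports accuracy as a function of
divergence.

## Synthetic data

* **Trees.** Random rooted binary topologies by uniform pairwise joining
  of lineages; every non-root edge gets an i.i.d. Exponential(mean)
  length (default mean 0.1 substitutions/site, a typical COI-scale
  branch). Deterministic per seed.
* **Provinces.** Random mode annotates each leaf independently with
  probability p (or draws an exact-size uniform sample, for matched-N
  comparisons); clustered mode gives one uniformly chosen clade of the
  requested size the focal province, plus optional independent noise
  leaves. Clustered annotation concentrates province members under shared
  internal edges, which is what drives its higher PD_E/PD_I — the
  qualitative signature of in-situ diversification.
* **Barcodes.** A uniform random root sequence evolves along a simulated
  species tree under Jukes–Cantor (per-branch substitution probability
  0.75(1 − e^{−4t/3}), substituted sites uniform over the other three
  bases) with per-edge mean length equal to the interspecific divergence;
  each individual then evolves from its species consensus by the
  intraspecific divergence (star phylogeny — no intraspecific structure).
  Defaults: 658 bp (the standard COI barcode), interspecific 0.05,
  intraspecific 0.005, i.e. a tenfold barcoding gap. No indels, no rate
  heterogeneity, no codon structure: the generator reproduces the
  statistical separation the analyses rely on, not COI realism, so
  passing tests certify the machinery, not field performance on real
  communities (where incomplete reference databases, misidentifications
  and shared haplotypes dominate the error budget).

## Problem sizes and numerics

The validation suite uses 200 random trees of ≤ 8 leaves with all-subset
enumeration for the PD oracle; N ≤ 10 with 5000 Monte-Carlo replicates
against exhaustive enumeration for rarefaction; 10 species × 3 sequences
× 658 bp over five divergence levels and five seeds for LOOCV recovery;
and 100 replicate 100-leaf trees for the clustered-vs-random contrast
(one-sided sign test). Oracle agreement is asserted at 1e-9; posterior
normalization at 1e-9; risk ties at 1e-12. All randomness flows from
single integer seeds through `numpy.random.default_rng`; per-component
seeds in the acceptance script are fixed offsets from the user seed.

## Known limitations

* PD statistics assume the input tree's branch lengths are meaningful
  substitutions/site; no correction for rate variation or tree
  uncertainty (bootstrap values are carried but unused).
* The assignment model treats sites as independent and species base
  frequencies as multinomial; linkage and within-species structure are
  ignored.
* Range standardization as defined maps the row maximum below 1 whenever
  the minimum risk is positive; cross-trial comparability is therefore
  approximate when minima differ.
* The LOOCV n−1 handicap described above depresses accuracy for species
  with few sequences; species-level accuracy under majority aggregation
  inherits the correlated failure of a species' trials.
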