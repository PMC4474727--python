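# pdbarcoder

Tools for two questions that recur in the molecular biogeography of
benthic invertebrates — worked out originally for COI barcodes of
Antarctic (Ross Sea) demosponges, but applicable to any branch-length
phylogeny with group annotations and any aligned barcode database:

1. **How much evolutionary history does a region hold, and how much of it
   arose in place?** For a marine province whose species form a leaf
   group *G* on a phylogeny, the *inclusive* phylogenetic diversity
   PD<sub>I</sub>(*G*) is the total branch length of the tree after
   trimming every leaf outside *G*; the *exclusive* diversity
   PD<sub>E</sub>(*G*) is the summed length of branches leading only to
   members of *G* — equivalently the total tree length minus
   PD<sub>I</sub> of the complement. A high PD<sub>E</sub>/PD<sub>I</sub>
   ratio indicates in-situ diversification rather than assembly by
   dispersal. Because sampling effort differs between provinces,
   PD<sub>I</sub> is rarefied: for every subsample size *k* = 1..*N* the
   expected PD<sub>I,k</sub> is estimated by Monte-Carlo leaf subsampling
   (or exactly, from the hypergeometric probability that a branch is
   missed).

2. **Can the barcode identify species?** A query sequence *S* is assigned
   to the candidate species *i* minimizing the expected loss
   R(*i*) = d(*S*, cons<sub>*i*</sub>) · (1 − P(*i* | *S*)), where d is the
   uncorrected p-distance to the species consensus and the posterior
   P(*i* | *S*) comes from a per-site categorical model over the
   database's segregating sites with Laplace pseudocount α = 1:
   P(*i* | *S*) ∝ ∏<sub>j</sub> (c<sub>ij</sub> + α)/(n<sub>ij</sub> + 4α).
   Accuracy is estimated by leave-one-out cross-validation with a genus
   fallback for singleton species, and per-trial risks are range
   standardized, R<sup>s</sup> = (R − min R)/(max R + min R), for
   comparison across trials.

A simulation module supplies random trees (exponential branch lengths),
random or clade-clustered province annotations, and Jukes–Cantor barcode
alignments with a built-in barcoding gap, so every stage can be validated
against known truth.

## Worked example

```python
from pdbarcoder import (PhyloTree, ProvinceMap, pd_report,
                        read_barcode_fasta, assignment_risk)

tree = PhyloTree.from_newick("((A:1.0,B:2.0):3.0,C:4.0);")
pmap = ProvinceMap.from_pairs([("A", "P1"), ("B", "P1"), ("C", "P2")])
r = pd_report(tree, pmap, "P1")
print(r.pd_inclusive, r.pd_exclusive, r.ratio, r.n)
# 6.0 6.0 1.0 2   -> P1's two species span 6.0 substitutions/site of the
#                    tree, all of it on branches private to P1

db = read_barcode_fasta(">x1|GenX_alpha\nACGT\n"
                        ">y1|GenY_beta\nAGGT\n>y2|GenY_beta\nAGGA\n")
res = assignment_risk("ACGT", db)
print(res.posteriors.round(6), res.risks.round(6), res.min_risk_species)
# [0.742268 0.257732] [0.       0.371134] GenX alpha
#   -> the query matches GenX alpha's profile at both segregating sites
#      (posterior 0.742, consensus distance 0), so its risk is 0 and the
#      call is GenX alpha; GenY beta carries risk 0.5 * 0.742 = 0.371.
```

The same operations are scriptable:

```
pdbarcoder simulate tree --n-leaves 100 --seed 1 --out tree.nwk
pdbarcoder simulate provinces --tree tree.nwk --mode clustered \
    --clade-size 20 --seed 2 --out prov.tsv
pdbarcoder pd report --tree tree.nwk --provinces prov.tsv --out pd.json
pdbarcoder pd rarefy --tree tree.nwk --provinces prov.tsv \
    --n-reps 1000 --seed 3 --out rarefaction.csv
pdbarcoder ssa loocv --db barcodes.fasta --out run
```

Outputs are CSV/JSON with the seed and a configuration hash embedded;
identical inputs and flags reproduce byte-identical files. Exit codes:
0 success, 2 input error, 3 invariant violation.

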