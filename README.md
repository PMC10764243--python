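# mbcdeg

Clustering-based differential expression analysis for RNA-seq count data.

Most differential expression (DE) tools test each gene separately and
return p-values; classifying the significant genes into expression
patterns is then a second, separate clustering step.  `mbcdeg` does both
at once: it fits a K-component negative-binomial mixture over per-gene
expression-effect vectors, identifies which mixture component represents
the *non*-differentially-expressed genes, and ranks every gene by its
posterior probability of belonging to that component.  It is aimed at
analysts with a genes x samples count matrix from a two-group (or
multi-group) comparison who want a DE ranking together with the
expression pattern of each gene — including in heavily asymmetric
experiments where more than half the transcriptome changes in one
direction, a regime where normalization-dependent methods struggle.

## The model

For gene *g* (= 1..G) in group *i* (= 1..I), the effect vector
β*_g* = (β*_g1*, ..., β*_gI*) holds the log deviation of each group's mean
expression from the gene's overall log mean, so Σ*_i* β*_gi* = 0; for two
groups, β*_g* is (½ log FC, −½ log FC).  Counts are modeled as negative
binomial with gene dispersion φ*_g* (Var = μ + φ*_g*μ²) and mean

&nbsp;&nbsp;&nbsp;&nbsp;E[y*_gj*] = exp(a*_g* + μ*_k,i(j)* + log f*_j*),

where a*_g* is a per-gene baseline, μ*_k* the shared sum-to-zero effect
vector of mixture component *k*, and f*_j* the per-sample CPM
normalization factor (10⁶ / library size), entering the mean as an added
offset.  The pipeline mirrors the classic three-stage flow — data
preparation, k-means++ seeding of the K centers from the per-gene effect
estimates, then EM — and returns the fitted centers μ*_k* and the G x K
posterior matrix *p_g*.

The non-DEG component is the one whose center has the smallest L2 norm
‖μ*_k*‖₂ = (Σ*_i* μ*_ki*²)^½: its shared effect is closest to "no change".
A gene's DE score is 1 − *p_g,k\**, the complement of its posterior
probability of non-DEG membership; rank 1 is the most differentially
expressed gene.  With K = 3 in a two-group design the three components
capture up-in-group-1 ("DEG1"), up-in-group-2 ("DEG2"), and non-DEG
patterns, so identification and pattern classification come out of a
single fit.

## Worked example

The package ships a generator for a 2,000-gene x 11-sample two-group
dataset (five group-A samples, six group-B): genes 1-360 are 4-fold up in
A, genes 361-400 are 9-fold up in B, and the remaining 1,600 genes are
flat — so 20% of genes are DE and 90% of the DEGs favor group A.

```python
import numpy as np
from mbcdeg import replica_sample_dataset, cpm_factors, run_pipeline, auc

counts, design, truth = replica_sample_dataset(seed=1)
norm = cpm_factors(counts)
result = run_pipeline(counts, design, norm.log_factor, K=3, seed=1)

print(np.round(result.model.centers, 2))
print("non-DEG cluster:", result.nondeg_index + 1)
print("AUC:", round(auc(result.de_score, truth), 3))
```

prints

```
[[ 0.04 -0.04]
 [-1.01  1.01]
 [ 0.74 -0.74]]
non-DEG cluster: 1
AUC: 0.997
```

The three centers recover the planted patterns: (0.74, −0.74) ≈
(log√4, −log√4) is the 4-fold-up-in-A cluster, (−1.01, 1.01) ≈
(−log√9, log√9) the 9-fold-up-in-B cluster, and (0.04, −0.04) the
near-zero non-DEG cluster, which the minimum-norm rule selects.  Ranking
all genes by DE score separates true DEGs from non-DEGs almost perfectly
(AUC 0.997).  The small displacement of all centers in the same direction
is the imprint of CPM normalization under asymmetric DE and is expected.

The same analysis from the shell:

```sh
mbcdeg simulate --genes 2000 --pdeg 0.2 --p1 0.9 --fc 4 --reps 5,6 \
    --seed 1 --out counts.tsv --truth truth.tsv
mbcdeg run --counts counts.tsv --groups A,A,A,A,A,B,B,B,B,B,B \
    --k 3 --seed 1 --out results.tsv
mbcdeg evaluate --scores results.tsv --truth truth.tsv
```

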