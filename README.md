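# locusgeo

Locus-aware geometric feature engineering and gradient-boosted
classification for prioritizing **regulatory SNPs** (rSNPs) among the
noncoding variants of GWAS-implicated loci.

## The problem

Genome-wide association studies implicate whole *loci* — groups of SNPs
in strong linkage disequilibrium (LD) — rather than single causal
variants. Within a locus, typically one variant is the regulatory SNP
(rSNP) and the remaining ~14–15 are non-functional control SNPs
(cSNPs). Supervised classifiers score each SNP from a table of
annotation features (conservation, chromatin state, TFBS overlap, …),
but the locus grouping itself carries signal: SNPs of one locus form a
"cloud" in annotation space, and the rSNP tends to sit at a different
typical distance from its neighbours than the cSNPs do.

## The method

For a SNP *s* with locus neighbourhood *L(s)* and a distance *d*, the
**intralocus radius** is the average distance to the other SNPs of its
locus:

```
λ(s|d) = 1/(|L(s)|−1) · Σ_{s′∈L(s), s′≠s} d(s, s′)
```

Radii are computed for five metrics — Canberra, Euclidean, Manhattan,
cosine (1 − cosine similarity) and Pearson (1 − correlation of the two
feature vectors) — on both the raw and min-max-scaled one-hot-encoded
feature matrix (ten combinations). For each combination, the radii of
rSNPs and cSNPs are modelled with class-conditional parametric
densities (normal for cosine/Pearson, log-normal for the rest, selected
by AIC), and each SNP receives the log-likelihood-ratio feature

```
LLR_d(s) = ln p_r(λ(s|d)) − ln p_c(λ(s|d))
```

(singleton loci: LLR = 0). The ten LLR columns are appended to the base
feature table and an xgboost gradient-boosted tree classifier
(binary-logistic objective, base score = rSNP/cSNP count ratio) is
trained. Evaluation uses **locus-coherent** cross-validation — an rSNP
and its LD-linked cSNPs never straddle folds, and radius-distribution
parameters are fitted on training folds only — with three metrics:
AUPVR (average precision), AUROC, and AVGRANK, the mean within-locus
rank of the true rSNP by descending score (lower is better; this models
the cost of post-GWAS follow-up, which examines each locus
top-score-first).

## Worked example

Generate a synthetic dataset of 30 loci whose rSNPs are displaced from
their locus centroid (radius bias, no direct feature signal), then
compare classifiers with and without the geometric LLR features on
identical locus-coherent folds:

```bash
locusgeo simulate --n-loci 30 --displacement 3.0 --seed 3 --out-prefix demo
locusgeo run-comparison demo.tsv demo.schema.yaml --k 3 --n-reps 2 --seed 0 --out demo.cmp.json
```

prints

```
AUPVR 0.0692 -> 0.2464; AUROC 0.5000 -> 0.7253; AVGRANK 7.7500 -> 5.3167
```

The base model sees nothing (AUROC 0.50, AUPVR ≈ the 0.069 class
prevalence — the displacement direction is random, so no single column
separates the classes), while the model with the ten LLR columns
recovers most of the geometric signal and more than halves the average
within-locus rank of the true rSNP. `demo.cmp.json` holds per-fold
metrics and 95% bootstrap confidence intervals over replication means.

Other subcommands expose each pipeline stage (`radii`, `radius-report`,
`llr-fit`, `llr-apply`, `cv-split`, `train`, `predict`, `evaluate`,
`tune`, `importance`) plus `grasp-filter`, which joins predictions with
a trait-association table and keeps genome-wide-significant SNPs
(p < 5×10⁻⁸) scoring at least 0.7.

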