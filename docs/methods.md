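# Methods

## Model and procedure

The pipeline scores noncoding SNPs for regulatory potential from a
typed annotation table in which every SNP belongs to one LD locus.
The stages are:

1. **Encoding.** Categorical features expand to one indicator column
   per declared level (one-hot, including levels unobserved in the
   data); continuous and integer features pass through. One-hot rather
   than k−1 dummy coding is used because the distance metrics should
   treat levels symmetrically. Indicator columns participate in
   scaling like any other column (idempotent when both levels occur).
2. **Scaling.** Min-max scaling, x → (x − min)/(max − min), fitted on
   an explicit subset of rows and applied *without clipping*; columns
   with max = min map to 0. Inside cross-validation the fit subset is
   always the training fold. Its purpose is to tame high-variance
   continuous annotations before the unbounded metrics (Canberra,
   Euclidean, Manhattan).
3. **Intralocus radii.** For each SNP, the mean distance to the other
   SNPs of its locus, under five metrics on both the unscaled and the
   scaled matrix (ten combinations). Pearson distance is 1 minus the
   sample correlation between the two SNPs' feature vectors (the
   entries of the vectors are the paired observations). Singleton loci
   have no radius.
4. **Class-conditional densities.** Per combination, the radii of the
   two classes are fitted by maximum likelihood with a normal
   (cosine/Pearson — bounded, roughly symmetric radii) or log-normal
   (the other six combinations — unbounded, right-skewed) model; an
   AIC-based automatic choice is available as a diagnostic and agrees
   with these defaults on simulated data.
5. **LLR features.** Each SNP's radius becomes
   ln p_r(λ) − ln p_c(λ) per combination; the ten columns are appended
   to the base table. Singleton-locus SNPs get 0 (likelihood ratio 1).
6. **Classification.** xgboost gradient-boosted trees,
   binary-logistic objective. Defaults: eta 0.1, gamma 10, 30 rounds,
   max_depth 7, subsample 1.0, colsample_bytree 1.0,
   scale_pos_weight 1. The base score (the prior before any trees) is
   the rSNP/cSNP *count ratio* of the data; a prevalence mode
   (rSNP/total) exists. A ratio ≥ 1 is clamped to 0.5 since the base
   score is a probability.
7. **Evaluation.** k-fold cross-validation replicated n times with
   distinct seeds. Metrics per validation fold: AUPVR (average
   precision), AUROC (Mann–Whitney normalization, ties half credit),
   AVGRANK (per locus, average rank of the rSNP(s) by descending
   score with tied scores receiving average ranks; locus values are
   averaged over loci). 95% confidence intervals are percentile
   bootstrap (1000 resamples) over replication means.

## Leakage discipline

Scaling parameters and radius-distribution parameters are estimated on
the training fold only; validation LLRs are evaluated under those
training-fold fits. Radii themselves are purely intralocus quantities
and loci never straddle folds, so no radius mixes training and
validation information. The test suite asserts bit-identity of all
training-fold artifacts under permutation of validation labels.

## Cross-validation design

Loci are sorted by descending cSNP count (ties shuffled under the
replication seed) and dealt to folds in serpentine order
(0…k−1, k−1…0, …), a deterministic heuristic that balances per-fold
SNP counts and class ratios while stratifying on locus size. Default
is 5 folds × 10 replications; both are configuration knobs. The
with-LLR and without-LLR arms of a comparison always consume identical
fold assignments and identical model seeds.

## Synthetic data generator

Each locus is a Gaussian "cloud": a centroid drawn with standard
deviation `centroid_sd` (default 3) per continuous feature, cSNPs at
centroid + N(0, `cloud_sd`²) (default `cloud_sd` 1), and one rSNP per
locus displaced from the centroid by `rsnp_displacement` in a uniformly
random direction before the same noise is added. Per-locus cSNP counts
are a shifted negative binomial (minimum 1) with mean `csnp_mean` 14.5
and dispersion 8, mirroring the ~14.5:1 class imbalance of curated
reference sets; 5% of loci are singletons (a lone rSNP), exercising
the likelihood-ratio-1 rule. Categorical columns draw a per-locus
dominant level with concordance 0.8. Optional `signal_features`
columns add a direct mean shift for rSNPs, for experiments where
non-geometric signal is wanted.

The generator emulates *geometry only*. It does not model LD decay,
allele frequencies, annotation semantics, correlated features, or
latent positives (undiscovered rSNPs among the controls). Passing
tests therefore demonstrate that the machinery extracts a
class-conditional radius bias when one exists and invents nothing when
it does not — not that any particular real annotation matrix carries
such a bias.

## Numerical conventions

- **Degenerate distances.** Cosine with a zero-norm vector and Pearson
  with a zero-variance vector are defined as distance 1 (similarity
  treated as 0), with a warning. Canberra terms with a 0/0 denominator
  contribute 0.
- **MLE.** Variance uses divisor n (true maximum likelihood),
  consistent with AIC = 2k − 2 ln L, k = 2. Log-normal fits replace
  non-positive samples by (smallest positive sample) × 10⁻³, logged.
- **Empirical binned LLR diagnostic.** 11 equal-width bins over the
  pooled radius range. The default reports the class-normalized
  density ratio ln[(N_r/ΣN_r)/(N_c/ΣN_c)], because the parametric
  feature is a ratio of probability *densities* and a raw count ratio
  would embed the class imbalance as a constant offset; a raw
  count-ratio mode is selectable. Bins where either class count is
  zero get +0.5 on both classes and are flagged. The classifier's
  features come from the parametric path, so this affects diagnostics
  only.
- **LLR clamp.** Feature LLRs are clipped to ±50 nats so far-tail
  validation radii under training-fold fits stay finite; 50 nats is
  far beyond any informative range. Clamping is logged.
- **Moments.** Skewness g1 = m3/m2^{3/2}; kurtosis is reported raw
  (m4/m2², normal → 3), not excess.
- **Ties.** Average ranks everywhere (AVGRANK, AUROC); precision-recall
  thresholds group tied scores.
- **Determinism.** Training, importance and fold assignment are
  deterministic under a fixed seed with single-threaded xgboost (the
  test default); multi-threaded runs may differ in the last bits.

## Problem sizes

The test and acceptance experiments use 200 loci with a mean of 14
cSNPs per locus (~2,900 SNPs), 20 continuous + 4 categorical features,
displacement 4 × cloud_sd for the biased condition and 0 for the null,
10 replications of 5-fold CV. These sizes give stable Monte-Carlo
bands (replication-mean AUPVR differences far exceed their spread)
while keeping a full run in the low minutes on one CPU.

## Known limitations

- The many-to-many structure of real LD (a cSNP linked to several
  rSNPs) must be resolved to a single locus_id upstream; the package
  requires a partition.
- The serpentine fold deal is one reasonable stratification heuristic;
  it is not an optimal balanced-partition solver.
- Grid search evaluates one fold assignment, not nested CV; reported
  tuning objectives are validation values, not unbiased generalization
  estimates.
- AVGRANK aggregates per locus, then averages loci; loci with several
  rSNPs average their ranks first. Alternative poolings exist.
- The GRASP-style filter applies p < 5×10⁻⁸ strictly and
  score ≥ 0.7 inclusively.
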