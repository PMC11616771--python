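# Methods

## Problem and model

The package predicts synthetic lethality (SL) between gene pairs. A pair
(g_a, g_b) — always stored with the lexicographically smaller symbol first,
so every order-dependent feature is well defined — is represented by k = 5
per-source feature vectors:

| source | width | content |
|---|---|---|
| `seq` | 1024 | elementwise absolute difference of protein-sequence embeddings |
| `ppi` | 64 | absolute difference of PPI-network node embeddings |
| `crispr_mut` | 4 | mean CRISPR dependency of each gene in cell lines where the partner is / is not mutation-altered |
| `crispr_expr` | 4 | same, conditioning on expression alteration (\|z\| > 1.96, strict) |
| `tissue` | 13 | survival Wald p, 4 conditional mean expressions, 6 co-expression (r, p) in tumour/normal/healthy, 2 CNA Spearman (rho, p) |

An *alteration* is a non-silent mutation, an expression z-score with
|z| > 1.96 (strictly), or a discrete copy-number score of exactly ±2. The
comparisons are strict by design; a z-score of exactly 1.96 is not an
alteration. Non-silent variant classes default to {missense, nonsense,
frameshift, splice_site, nonstop, inframe_indel} and are configurable.

The model is an early–late integrated ensemble: k single-source tree
ensembles plus one early-integration model on the concatenated
1109-dimensional feature vector, all sharing one hyperparameter
configuration. With p_i the mean 5-fold validation AUPRC of submodel i,
the weights are w_i = p_i / Σ_j p_j (uniform fallback if all p_i = 0) and
the prediction is the weighted average of submodel class probabilities,
ŷ = Σ_i w_i ŷ_i, which is a convex combination and therefore lies in [0, 1].

## Embeddings

Sequence embedding is pluggable behind a one-method `Embedder` interface
(dimension + deterministic `embed`), so precomputed protein-language-model
vectors can be imported as TSV tables. The built-in `KmerHashEmbedder`
hashes overlapping 3-mers into signed buckets (salted by its seed) and
L2-normalizes; sequences sharing subsequences land near each other, which
is the property the pair features rely on.

PPI node embeddings use node2vec-style second-order random walks
(defaults p = 1, q = 1, 10 walks per node, length 80, window 10, d = 64)
followed by a closed-form skip-gram: positive PMI of the window
co-occurrence matrix, factorized by SVD, rows scaled by sqrt of the
singular values. This is deterministic for a fixed seed (walks use one
seeded generator; the SVD sign ambiguity is resolved by the
largest-magnitude loading). Graphs smaller than d are zero-padded so the
64-column contract always holds; isolated nodes get zero vectors. Genes
absent from the PPI graph or the embedding table yield all-NaN feature
rows; pairs are never dropped at featurization time.

## Tissue features and survival

Expression levels are log2(x+1)-transformed before averaging and
correlation; z-scores serve only for alteration calling. Correlation
p-values are two-sided; compartments need ≥ 3 samples and non-constant
vectors, otherwise NaN. The survival feature is the Wald p-value of the
co-mutation indicator in a Cox proportional-hazards fit (lifelines, Efron
ties) with age, sex and cancer-type covariates; single-level covariates
(single-sex or single-cancer cohorts, constant age) are dropped
automatically to keep the information matrix non-singular, and degenerate
or non-converged fits return NaN rather than raising. The gene-family
variant groups patients by "alteration in ≥ 1 member of each family",
reports the (Fam1 and Fam2) Cox result plus one-family-only / unaltered
subgroups, and emits Kaplan–Meier step functions per group; its p-value is
suppressed below `min_group_size` co-altered samples (default 5, because
co-mutation groups are typically tiny and a Cox fit on a handful of
patients is not interpretable).

## Fitting, imputation and search

Missing features are imputed by per-column training medians, frozen at fit
time (validation folds use their own training-fold medians; the final
model stores full-training medians for `predict`). One hyperparameter
configuration is shared across all k+1 submodels. The declared grid is
trees ∈ {100, 200, 500}, max depth ∈ {4, 8, unlimited}, min leaf ∈
{1, 5, 10} (gradient boosting adds learning rate ∈ {0.05, 0.1, 0.3}); the
search is exhaustive when the grid fits in the budget (default 25 trials)
and otherwise sequential model-based: a random-forest surrogate over the
numerically encoded grid picks the next trial by mean + sd upper bound.
Trials are scored by the mean over 5 stratified folds of the ensemble's
validation AUPRC, where each fold's ensemble uses that fold's normalized
submodel AUPRCs as weights. Random-forest submodels are sklearn
`RandomForestClassifier`; gradient-boosted submodels are xgboost
(`hist`/`lossguide`; unlimited depth maps to `max_depth=0`, min leaf to
`min_child_weight`).

## Evaluation protocols

Standard runs: one global stratified 80/20 pair-disjoint split, then per
run independent seeded undersampling of the majority class within train
and, by default, within test (`balance="train"` leaves the test set
imbalanced). Double gene holdout: per run the gene universe is partitioned
and only pairs with both genes on one side are kept, so train and test
share zero genes (asserted, not assumed); the gene-side test fraction q
solves q²/(p²+q²) = 0.2 (q = 1/3), and partitions leaving a side
single-class are resampled up to 50 times. Cross-label-source runs train
on one label study and test on another with overlapping pairs removed from
the test side. AUPRC is average precision (step interpolation — trapezoidal
PR interpolation is optimistic); AUROC is the normalized Mann–Whitney
statistic. Paired comparisons use the two-sided Wilcoxon signed-rank test;
zero differences are dropped, and for ≤ 15 informative pairs the p-value
is computed by exact enumeration of all sign patterns (valid under tied
ranks, where textbook exact tables are not).

Category importance permutes all columns of one source jointly with a
single row permutation (preserving within-category structure), rebuilds
the concatenated block from the permuted source, and reports the mean over
20 permutations of (1 − AUPRC)_permuted / (1 − AUPRC)_original. The
identity permutation gives exactly 1; a zero original error yields an +inf
sentinel with a warning. The mean of per-permutation ratios is the
headline number (not the ratio of mean errors).

## Synthetic data

The generator emits every input the pipeline consumes, with planted,
recoverable effects; its defaults are the study conditions used by the
acceptance checks (200 genes, 300 cell lines, 600 patients, 80 SL + 80
non-SL pairs, δ = 1.0, r = 0.6, h = 0.5). SL pairs form a gene-disjoint
matching so per-pair correlation targets never conflict.

* Sequences are uniform 240-mers; SL partners share a 60-residue inserted
  motif (domain-scale, long enough for 3-mer hashing to see it).
* The PPI list mixes background edges with random evidence classes and
  3 shared experimental-evidence neighbours per SL pair.
* Dependency scores are N(0, 0.3); for an SL pair the dependency of each
  gene drops by δ in cell lines carrying a non-silent mutation in the
  partner. Tying the planted shift to the mutation channel (genetic loss is
  what creates dependency) makes `crispr_mut` the designed-dominant source,
  giving the weight-recovery check a well-defined answer.
* Tumour expression follows a one-factor model (per-gene communality
  U(0, 0.7)), so *all* pairs show background co-expression, as real tumour
  programs do; SL-pair idiosyncratic noise is additionally correlated so
  their total correlation is exactly r. r = 0 plants nothing (forcing
  exactly-zero correlation would itself be a detectable signal). Normal and
  healthy compartments share the factor structure but carry no pair signal.
* Survival is exponential (baseline median ≈ 42 months) with the hazard
  multiplied by h for patients co-altered in ≥ 1 SL pair; censoring is
  uniform administrative.
* `effect_penetrance` < 1 lets a fraction of labelled SL pairs carry no
  effects at all — mimicking labels from non-matching contexts — which
  guarantees irreducible test error, needed for well-defined importance
  ratios.

`verify_planted_effects` recovers δ (conditional-mean contrast), r (mean
SL-pair Pearson on the log scale; excess over background when r = 0) and h
(Cox fit on the planted co-alteration indicator), flagging deviations
beyond 3 standard errors.

What the generator does not emulate: mutational signatures and
mutual-exclusivity structure (alterations are independent Bernoulli per
sample and gene), copy-number segments (per-gene independent discrete
scores), realistic marginal distributions of any cohort, and gene-family
structure. Passing tests therefore demonstrate that the framework recovers
the kinds of signal it was built to exploit at realistic sample sizes —
not that it reaches any particular performance on real cohorts.

## Problem sizes and numerical choices

The packaged checks run at desk scale by choice: end-to-end recovery uses
10 seeded worlds at the default conditions with a compact declared grid
(200 trees, depth 8, min leaf {1, 5}; 2 trials), importance uses
100-gene worlds with penetrance 0.6, the null calibration uses 200
replicates at n = 300. Submodels run single-threaded for bit
reproducibility. Ties in ranking are broken lexicographically by pair;
ties in the hyperparameter search by trial order. Empty-selection means,
undefined correlations and degenerate survival fits all propagate NaN,
which the imputation layer absorbs at fit/predict time.

## Known limitations

Pan-cancer ensembling assumes per-cancer models share feature-block
layout. The SMBO surrogate is a point-estimate forest (no proper
acquisition integral), adequate for the small declared grids. The walk
embedding is a spectral stand-in for SGD-trained skip-gram: distances are
comparable, individual coordinates are not. Per-pair survival features are
computed by one Cox fit per pair, which dominates featurization time on
large pair lists.
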