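# Methods

This note documents the statistical machinery in `cernakit`: the models,
the tunable parameters and their defaults, what the synthetic cohort does
and does not emulate, and the numerical and design choices that were
genuinely open.

## Normalization and abundance filtering

Sequencing-depth correction uses the median-of-ratios convention: for each
gene with strictly positive counts in every sample, the ratio of each
sample's count to the gene's geometric mean is formed, and a sample's size
factor is the median of these ratios, rescaled so the factors have
geometric mean exactly 1. Genes containing any zero are excluded from the
reference; if no zero-free gene exists the estimator refuses (no
pseudo-count fallback), because a hand-checkable oracle was preferred over
robustness to pathological inputs. FPKM is counts·10⁹/(length·library
size). Low-abundance genes are removed before testing: a gene is kept if
its FPKM exceeds a class threshold (1.0 for mRNA and miRNA, 0.1 for lncRNA,
which are systematically lowly expressed) in at least ⌈0.1·n⌉ samples. The
filter runs *before* the differential test so the multiple-testing burden
counts only tested genes.

## Differential expression

Counts are modeled as negative binomial with variance μ + αμ². For each
tumor stage vs normal, the per-gene log fold change is
log₂((μ̂_T + 0.5)/(μ̂_N + 0.5)) on normalized counts (the 0.5 pseudo-count
keeps it finite when one group is all zero). Dispersion α is estimated per
gene by method of moments within each group, pooled with (n−1) weights and
floored at 10⁻⁸; sub-Poisson moment estimates therefore fall back to
Poisson-level variance, which is conservative. The Wald statistic uses the
delta-method standard error of the log ratio and is referred to a
t distribution with n₁+n₂−2 degrees of freedom rather than a normal — at
group sizes in the tens, the dispersion estimate is noisy and the normal
reference is visibly anticonservative, while the t reference holds the
empirical type-I error at ~0.05 (checked by null simulation at 2,000 genes,
20 vs 20, α = 0.1). No shrinkage, outlier filtering or multi-factor design
is attempted: downstream logic needs stage-consistent DE calls, not
refined effect estimates. "Common" DEGs must pass |log₂FC| ≥ 1 and
BH FDR < 0.01 in all four stage comparisons *with the same sign*; the
direction-consistency requirement is this package's reading of a
stage-intersection Venn analysis, recorded as a design decision.
Benjamini–Hochberg adjustment passes NA statistics through without
counting them in m.

## ceRNA module scoring

Co-expression is Pearson correlation of log₂(normalized count + 1) over
all samples (tumor and normal pooled — the condition contrast is part of
the co-expression signal being exploited), with a two-sided p-value from
the t transform on n−2 df. Retention is strict and signed: r > 0.8 and
p < 0.05. The shared-miRNA tail probability is computed by direct
summation of the hypergeometric pmf in log-gamma space, which is exact to
~10⁻¹² against integer-binomial enumeration and stable for any universe
size. The miRNA universe is deliberately *internal*: DE miRNAs with at
least one retained interaction. Using the full annotation would make N
depend on an external database and silently deflate every p-value.
Modules require BH FDR < 0.05 across all tested pairs and at least
`min_shared` (default 1) shared miRNAs. The network gets one lncRNA–miRNA
and one miRNA–mRNA edge per shared miRNA per module, deduplicated across
modules; node degree ranking breaks ties lexicographically so output is
deterministic.

## Survival analysis

Kaplan–Meier estimation, the two-group log-rank test and Cox proportional
hazards regression (Efron tie handling — survival times have day
resolution, so ties are routine) are delegated to `lifelines` behind this
package's interface. Expression is dichotomized at the median with ties
assigned to the low group.

The module risk-score classifier needed a real design decision. The naive
construction — fit a multivariate Cox model on the module's three RNAs,
compute each patient's linear predictor Σβᵢxᵢ, median-split, log-rank —
tests a score on the same patients it was fitted to, and its null
log-rank p is *not* uniform: simulation here gives a p < 0.05 rate of
≈0.17 under three pure-noise covariates, and ordinary K-fold cross-fitting
only reduces it to ≈0.11 because the fold-wise fits are correlated (the
pre-validation pathology). The adopted design keeps the honest size
without discarding samples: patients are dealt round-robin into K = 3
folds, fold k is scored by a model trained on fold k+1 **only**, each fold
is median-split on its own scores, and the groups are compared with a
fold-stratified log-rank statistic. Each fold's labels are then
independent of its own outcomes, and no two folds test each other's
training noise, so the fold contributions are uncorrelated and the
statistic is asymptotically χ²₁ under the null (verified: p < 0.05 rate
0.035–0.055 over 200 null replicates) while a planted hazard effect of
β = 0.8 at ~300 tumor samples is detected at p ≈ 10⁻¹⁴. The *reported*
coefficients still come from the full-cohort multivariate fit (they are
the interpretable effect sizes); covariates are z-scored first so betas
are comparable across RNAs, and a |r| > 0.999 pair among the three RNAs is
refused as collinear. The direction label is "negative" when the high-risk
group fares worse (positive log HR of the high-group indicator).
Consequence of the fold-wise split: the high/low groups can differ in size
by up to one patient per fold rather than one overall.

## Regulator importance

For each target gene, an ensemble of 500 extremely randomized regression
trees predicts the standardized target from the candidate TFs
(`ExtraTreesRegressor`, all features considered per node, one random
threshold per feature, **no bootstrap** — resampling would break exact
invariance to sample order, which the randomized-threshold ensemble
retains). Importance of a TF is the total weighted variance reduction of
its splits, averaged over trees, as a fraction of target variance; the
importances for a target therefore sum to at most 1, and a target that is
an exact copy of one TF attributes ≈0.93 to it.

A raw training-impurity total is useless for nulls (a fully grown forest
explains any target perfectly), so splits must clear an admission gate:
`min_variance_reduction`, defaulting to 10/n of the target variance. A
spurious split on an unrelated regressor gains ~χ²₁/n of variance, so the
default gate admits it with probability ≈0.002 regardless of sample size,
and pure-noise targets score ≈10⁻³ or less — safely below the 0.005
retention cutoff. The price is resolution: weak true effects need several
hundred samples to clear the gate, and the operating characteristics
quoted above were established at n = 2,000. Retained regulon edges
additionally require Spearman ρ above a cutoff whose default, 0.03, merely
encodes "positively correlated"; it is exposed as a parameter because it
is unusually permissive and may deserve a stricter value in practice.
Cis-regulatory motif confirmation of regulon edges is out of scope (it
requires external motif-ranking databases); the regulons here are
co-expression drafts and include indirect targets.

## Synthetic cohort

The generator emulates a staged tumor/normal bulk cohort at desk scale.
Defaults (all overridable in `SimulationConfig`):

| parameter | default | meaning |
|---|---|---|
| n_normal / n_t1..t4 | 30 / 34, 55, 10, 6 | sample sizes, proportional to a real LUAD cohort's 59 / 168, 276, 47, 19 split |
| n_mrna / n_lncrna / n_mirna | 400 / 150 / 120 | genes per class |
| n_de_* | 40 / 20 / 40 | DE genes per class (includes planted genes) |
| n_planted_triplets | 8 | lncRNA–mRNA pairs with shared miRNAs |
| planted_log2fc | 2.0 | tumor-vs-normal shift of every DE gene, consistent across stages |
| nb_dispersion | 0.02 | NB dispersion α, typical of deeply sequenced bulk tissue |
| latent_corr | 0.9 | target log-scale Pearson r of planted pairs |
| shared_mirnas_per_triplet | 5 | miRNAs targeting both members, drawn from DE miRNAs |
| background_edge_prob | 0.01 | Bernoulli miRNA→target edges outside the planted ones |
| survival_beta / baseline_hazard / censor_rate | 0.8 / 10⁻³ per day / 0.3 | hazard model for tumor samples |

Counts are NB draws around log-normal baseline means with a per-sample
depth factor (log₂-normal, σ = 0.2). Each planted pair shares a mean-one
log-normal latent factor whose variance is set from the pair's predicted
log-scale NB noise so that the achieved correlation ≈ `latent_corr`; the
achieved value is validated empirically (≈0.96 at defaults) rather than
imposed exactly. Planted pair members share their fold-change direction
(the condition contrast is part of real co-expression); planted miRNAs
take free directions — no miRNA anti-correlation constraint is imposed.
Survival times are exponential with hazard
baseline·exp(Σβ_m·z_m) where z_m is the standardized latent score of
module m over tumor samples; only the first planted triplet carries a
nonzero β by default, so recovery of β by Cox regression is not attenuated
by omitted correlated hazards. Censoring is administrative at the
(1−censor_rate) quantile of the drawn times; times are rounded to whole
days (floor 1), which deliberately produces ties. All randomness flows
through one `numpy.random.Generator` (PCG64), so a fixed seed reproduces
the cohort byte-for-byte.

What the generator does **not** emulate: batch effects, GC/length bias,
compositional (library-size) artifacts beyond a scalar depth factor,
overdispersion heterogeneity across genes, isoform structure, read-level
noise, non-proportional hazards, and informative censoring. Passing the
planted-recovery tests therefore shows the pipeline's logic is correct
under its own model assumptions, not that the thresholds are optimal for
any particular real cohort — the headline numbers of the motivating study
(network size, specific hub genes) depend on real TCGA/GEO data and
external interaction databases and are reference points, not test
expectations.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run everything at the desk
scale above (≤2,000 genes, ≤335 samples, 200-replicate calibrations,
50-seed operating-characteristic checks), which completes in a couple of
minutes on one CPU. Every stochastic step takes an explicit seed; ensemble
seeds for per-target tree fits are derived with `numpy.random.SeedSequence`
from (seed, target index) so results are independent of target order.
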