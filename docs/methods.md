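# Methods

## The screening model

The pipeline treats pair discovery as a sequence of filters over a gene ×
sample log2 expression matrix with class labels (immune checkpoint /
lncRNA / other) and clinical annotations. Each filter is deliberately
simple and rank- or threshold-based; the statistical weight of the method
sits in the two places where chance must be controlled explicitly — the
dual co-expression criterion for accepting a pair, and the permutation
null for calling a pair prognostic.

### High-expression rules on immune-cell panels

Panels are quantile normalized (every sample column is mapped onto the
common per-rank mean vector; ties keep input gene order) and batch
adjusted by per-(gene, cell type) mean-centering: each batch's samples are
shifted so all batch means equal the cell type's sample-weighted grand
mean. This is the minimal location adjustment; it removes additive batch
offsets exactly and preserves each gene's within-cell-type mean. A full
empirical-Bayes adjustment is out of scope — on the Gaussian additive
batch model the generator produces, mean-centering is already exact.

Genes are ranked *within their class* in each cell type (checkpoints
against checkpoints, lncRNAs against lncRNAs), because the two classes
have very different expression distributions and the selection rules are
stated per class. Ties break lexicographically by gene id so results are
independent of sample order. "Highly expressed" means a class-wise rank
quantile strictly above `high_expr_quantile` (default 0.5, the top half).
A checkpoint is kept when high in at least one cell type. A lncRNA is
*immune-specific* when high in exactly one cell type and *immune-general*
when high in more than `ceil(T/2)` of T cell types (more than nine of
eighteen). "Exactly one" is an interpretation: the alternative reading
("at least one") would make the general rule redundant. Counts between
2 and ceil(T/2) fall in neither class and are excluded.

Monotonicity caveat: raising the quantile cutoff can only shrink the
per-cell-type high flags, hence the checkpoint and immune-general sets —
but the immune-specific set ("exactly one") is not monotone in the flags,
since a gene high in two cell types can *enter* the set when the cutoff
rises. The property tests assert monotonicity only where it holds.

### Infiltration scoring and ICR grouping

Per-sample enrichment uses the weighted running-sum statistic: genes are
ranked per sample (rank N = highest, ties broken by gene id), and the
score is the sum over the descending walk of the weighted in-set ECDF
(weights rank^0.25, normalized within the set) minus the out-set ECDF.
Scores depend only on within-sample ranks, so they are invariant under
strictly monotone per-sample transforms and need no cross-sample
normalization. Raw scores are used for sample selection; the response
module min-max normalizes pair-panel scores to [0, 1] because its
classifiers compare scores across samples.

Sample selection keeps the top 75% by immune score with a nearest-rank
convention: the cut is the (floor(0.25·n)+1)-th smallest score and
boundary ties are retained (conservative: never drops a sample that ties
the cut; when all scores are equal, everything is kept).

ICR grouping is consensus clustering with k fixed at 2: 100 resampling
rounds, each drawing 80% of samples without replacement and running
k-means on gene-standardized ICR-panel expression; the consensus entry of
a sample pair is its co-clustering frequency among co-drawn rounds; final
labels come from average-linkage hierarchical clustering of
1 − consensus cut at two groups, and the group with higher mean ICR
expression is "high". k-means is the inner algorithm of choice for
continuous standardized expression; the hierarchical consensus cut
mirrors the reference behaviour of resampling-consensus implementations.

Differential expression between ICR groups is a per-gene Welch t-test on
the log2 values (group sizes and variances are not assumed equal) with
linear fold change 2^Δ. P-values are used raw at α = 0.05; a
Benjamini–Hochberg toggle exists but is off by default, matching the raw
per-test cutoffs used throughout the screen.

### Pair acceptance

A candidate pair must pass both routes:

* **Pearson**: |r| strictly greater than 0.3 and two-sided P < 0.05 from
  the t-transform of r on n−2 degrees of freedom. The sign of r labels
  the pair positive or negative.
* **Mutual information**: plug-in MI (bits) on equal-frequency marginal
  bins, B = max(2, floor((n/5)^(1/3))) per axis, with an empirical
  permutation null on one margin; p = (1 + #{MI_perm ≥ MI_obs})/(B_perm+1),
  significant at α = 0.05.

Equal-frequency (rank) binning makes MI exactly symmetric and invariant
under monotone transforms, so the MI route genuinely differs from the
linear Pearson route and their intersection is informative. The
cube-root bin-count growth keeps the plug-in bias — approximately
(B−1)²/(2n ln 2) bits under independence — below ~0.01 bits at n = 10⁴;
a square-root rule would inflate it an order of magnitude. MI permutation
counts below 19 are rejected because they cannot resolve p < 0.05. The
*coincidence rate* — the fraction of Pearson-accepted pairs confirmed by
MI — summarizes the agreement of the two routes per cohort.

### Networks and hubs

Accepted pairs form a bipartite graph per cohort. The scale-free summary
is R² of the ordinary least-squares line through log10(frequency) versus
log10(degree), one point per observed degree value (≥3 distinct degrees
required); this descriptive fit is reported instead of a maximum-likelihood
exponent because the quantity of interest is the goodness of the log-log
line, not the exponent. Hubs are the top 5% of nodes by degree with
k = ceil(0.05·n) and boundary ties included; ICP and lncRNA nodes are
pooled for the cutoff but keep side labels. Across cohorts, hubs in ≥6
cohorts (i.e. more than five) are *common*, in exactly one *specific*,
otherwise *other*. Similarity between cohorts counts shared checkpoints,
lncRNAs, or pairs, normalized by the smaller set (Jaccard available via
config); min-normalization lets a small cohort nested in a large one
score 1.

### Survival screen

For each accepted pair: samples with complete survival/age/sex data are
split 50/50 at random (training gets the extra sample on odd n); a Cox
proportional-hazards model with covariates (z-scored checkpoint
expression, z-scored lncRNA expression, age, sex) is fitted on the
training half by Newton optimization of the Efron-tie partial likelihood
(step halving, tiny ridge on the Hessian, convergence at step < 1e-8);
held-out samples get the gene-only risk score with z-statistics frozen
from training; the held-out median splits them into high/low strata
compared by the standard two-group log-rank test. "Standardized
coefficient" is implemented as z-scored covariates (not coefficient/SE),
so coefficients are per-SD log hazard ratios and the risk score is
scale-free.

The permutation null jointly permutes the (time, event) columns across
all usable samples and re-runs fit → score → log-rank on the *same*
split. Permuting outcomes (rather than covariates) preserves both the
survival marginal and the covariate correlation structure, giving an
exchangeable null for the outcome association; holding the split fixed
isolates that null from split-to-split variability. Failed null
replicates (non-convergence, degenerate strata) are dropped and the
denominator adjusted: p = (1 + #exceedances)/(#valid + 1). With the
default 1000 permutations the smallest attainable p is ~0.001; the
observed statistic is the log-rank chi-square (not the Cox Wald), since
the held-out stratified survival contrast is the quantity of interest.
The test suite verifies the screen's type-I error at the nominal 5% over
200 null pairs, and both Cox and log-rank against lifelines.

The Cox solver and log-rank statistic are implemented in-package on plain
arrays (reverse-cumulative risk-set sums, vectorized over event times)
because the permutation screen refits the model hundreds of times per
pair; a fit takes well under a millisecond at cohort sizes of a few
hundred. Nomogram and calibration-curve rendering are out of scope; the
fitted quantities a plotting layer would need are all exported.

### Response prediction

Candidate pair features are per-pair mean expression (the average of the
two member genes). The LASSO stage standardizes features, scores a 20-point
logarithmic penalty grid by stratified 5-fold cross-validated deviance,
and picks the penalty by the one-standard-error rule; the selected panel
keeps only features nonzero both in the full-data refit and in every CV
training fold at that penalty. The fold-stability filter is there because
a single L1 path at n of a few hundred admits fold-specific spurious
features; requiring cross-fold agreement removes most of them without
touching genuinely informative features. An all-zero selection is a
flagged outcome, not an error.

The SVM stage is a linear soft-margin classifier (C = 1) on standardized
features with training-frozen statistics; responder calls use the sign of
the decision function (LASSO-logistic uses probability 0.5). The feature
recipe is configurable: per-pair mean features (default), the aggregate
pair-panel enrichment score, or both. Per-pair features are the default
because the aggregate enrichment score of a panel's gene union dilutes a
few informative pairs among spurious panel members and gives the
classifier no way to weight pairs individually; per-pair features let
the SVM learn those weights and track the attainable AUC much more
closely on the reference study. Cross-cohort
application recomputes features on the new cohort (enrichment scores are
per-sample and rank-based, so no cross-cohort batch correction applies).

ROC/AUC is the threshold sweep with Mann–Whitney AUC (ties credited 0.5),
checked against exhaustive pair counting. The predicted-responder versus
ICR-group association uses the two-sided Fisher exact test (scipy's
hypergeometric implementation, cross-checked against full enumeration).

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
directly on the log2 scale (Gaussian values, not counts — every
downstream statistic operates on normalized log-scale arrays, and
platform-level preprocessing is out of scope).

**Immune panels.** Baseline expression is Normal(5, 1) per observation;
designated immune-high genes gain +2 log2 units in their designated cell
types; per-(gene, batch) offsets are Normal(0, batch_shift_sd), centered
per gene so batch effects perturb between-batch location without shifting
a gene's overall level. Designation is an exact deterministic schedule:
specific lncRNA i is high in cell type i mod T; each general lncRNA is
high in T−1 greedily-balanced cell types; together the designed genes
fill each cell type's top-half rank slots exactly. Planted genes carry a
below-median baseline (4.0) outside their designated cell types. Both
choices exist for identifiability: with an iid baseline and partial slot
filling, observation noise promotes arbitrary genes into the top half and
a planted "specific" gene accumulates chance high-counts across the other
17 cell types, making the exactly-one rule unrecoverable by *any*
method. Null genes keep the plain iid model, so on a panel with no
planted structure the specific/general rates match the combinatorial
null (binomial, p = 0.5 per cell type) — a property the tests check.

**Tumor cohorts.** A latent infiltration score u ~ Normal(0, 1) per
sample loads on ICR-panel and immune-signature genes with
`infiltration_effect` (default 1.0) and on checkpoint/lncRNA genes with
`target_loading` (default 0.5, enough for the ICR-group differential
screen to pass them through). Planted pairs receive jointly Gaussian
residuals with the configured correlation, so the planted ρ is the
partial correlation given u and the total correlation is
(a² + ρ)/(a² + 1) at loading a — e.g. 0.68 for ρ = 0.6 at a = 0.5,
while unplanted pairs correlate at a²/(a²+1) = 0.2, below the 0.3
acceptance threshold. Survival times are Exponential with log-hazard
Σ β_p·(pair mean − 5) over prognostic pairs (centering at the baseline
mean only re-parameterizes the baseline hazard) and baseline median 1000
days; censoring is administrative at the empirical quantile matching
`censor_rate`, which controls the event fraction exactly. Response labels
are Bernoulli with logit Σ w_p·(pair mean − 5); age ~ Normal(60, 10) and
sex ~ Bernoulli(0.5) are pure confounder noise.

**Reference study conditions** (the SimConfig defaults, used by the
acceptance checks): two cohorts of 300 samples; a 20 × 20
checkpoint/lncRNA grid with 20 planted pairs (ICPᵢ, LNCᵢ, ρ = 0.6); the
first five pairs prognostic at β = 0.8; pairs six to eight driving
response at w = 2.0; 20 ICR genes and 50 signature genes among 500 genes
total; an 18-cell-type panel with 50 samples per type in 3 batches.
The test suite and the acceptance script run the survival screen at 200
permutations (the config default is 1000) to keep the whole run around a
minute; power at these settings is already near ceiling for the planted
effects.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: count noise and depth normalization, non-Gaussian
expression marginals, probe-level artifacts, non-proportional hazards,
informative censoring, population structure among patients, and
correlation between the confounders (age, sex) and expression. The
generator validates the *machinery* (rules applied exactly, estimators
unbiased, nulls calibrated), not robustness to these real-data features.

## Numerical and degenerate-input conventions

Thresholds are strict where the rules say "larger than" (|r| > 0.3,
P < 0.05, fold change > 1). Ties: rank ties break by gene id everywhere
ranking occurs; hub and infiltration cutoffs retain boundary ties.
Permutation p-values use the add-one form (1+k)/(n+1) and can never be
zero. Constant vectors are errors in correlation and Cox covariates;
empty Pearson sets make the coincidence rate an explicit error rather
than a NaN. The consensus matrix is symmetrized and unit-diagonal by
construction; a sample pair never co-drawn (impossible at the default
100 × 80% resampling, but possible in principle) gets consensus 0.
All randomness flows from one seed through per-stage substreams
(BLAKE2-hashed stage labels feeding a SeedSequence), so stages are
reproducible independently of each other's draw counts.

## Known limitations

* The batch adjustment is location-only; scale batch effects would
  survive it (the generator produces none).
* The MI permutation p is conservative when MI takes few distinct values
  (small n with 2 bins); at n ≥ 200 the discreteness is negligible.
* The survival screen drops samples with missing age/sex rather than
  imputing; cohorts with systematic missingness would shrink.
* With near-separable response data the LASSO deviance curve is flat near
  its minimum; the one-SE rule plus fold-stability keeps panels small,
  but the selected set is not unique under strong feature correlation —
  prediction is stable, membership of correlated duplicates is not.
* Consensus clustering determinism holds for a fixed seed and library
  stack; k-means label order is made irrelevant by the consensus matrix,
  but exact consensus values depend on the resampling stream.
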