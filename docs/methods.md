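# Methods

`plasmasig` implements a plasma-proteome biomarker discovery workflow for
cohorts treated with neoadjuvant chemotherapy (NCT): starting from a
label-free quantification (LFQ) matrix and a clinical table, it filters and
imputes the matrix, normalizes it against endogenous stable proteins, calls
differentially abundant proteins between pathological-complete-response
(pCR) and non-pCR groups, selects a marker panel by random-forest backward
elimination, evaluates SVM/RF classifiers over repeated random trisections,
and stratifies survival by maximally selected rank statistics and Cox
regression.  A synthetic-data generator reproduces the statistical
structure each stage assumes, so the whole pipeline is testable without
any external data.

## Synthetic study generator

The generator emulates the post-search product of a single-run LC-MS/MS
plasma study: a 51-sample x 548-protein abundance matrix and a clinical
table with three survival endpoints.

Abundance model (natural-log scale):

    log x_is = b_i + delta_i * g_s + u_s + eps_is

* `b_i ~ N(mu, tau^2)` — protein baselines; `mu = 18`, `tau = 1.5` give
  intensity spans typical of plasma LFQ (~6 orders of magnitude).
* `delta_i` — group effect, nonzero for `n_differential = 4` planted
  markers (one up in pCR, three up in non-pCR), specified as a log2 effect
  size (default 1.2) so it aligns with the volcano axis.
* `u_s ~ N(0, 0.3^2)` — per-sample multiplicative bias (loading, depletion,
  drift); this is exactly the nuisance NSF normalization removes.
* `eps_is ~ N(0, 0.35^2)` — measurement noise (~35% CV); the four planted
  "housekeeping" proteins use 0.05 and sit two baseline SDs above the mean
  abundance, mimicking stable abundant plasma proteins.

Missingness is missing-not-at-random: a cell is missing with probability
`sigmoid(-1.80 - 2.0 * z_is)` where `z` is the standardized log abundance.
The intercept was set so that roughly 55% of proteins pass the 80% presence
filter (~305 of 548), matching the attrition the workflow is designed
around; low-abundance proteins are lost preferentially, which motivates
local least squares imputation from fully observed (abundant, correlated)
proteins.

Clinical covariates follow a fixed subtype mix (20 : 5 : 5 : 21 for
HR+/HER2-, HR+/HER2+, HER2+, TN at n = 51) with 15 pCR cases allocated
2 : 3 : 2 : 8 across subtypes; grade-3 frequency is subtype-dependent.

Survival uses latent exponential proportional-hazards clocks: distant
metastasis M, additional local recurrence L, and post-metastasis death
M + G, each with rate multiplied by `exp(eta)` where `eta` is linear in
standardized log abundances of designated proteins (per-endpoint
coefficients).  Administrative censoring is uniform over 24–84 months.
DFS events are `min(L, M)`, DMFS events are M, deaths occur only after
metastasis — so a DMFS event always implies a DFS event, and death without
recurrence censors DFS/DMFS (competing risks are out of scope).  The
baseline metastasis rate is calibrated by quadrature + root finding so the
expected DMFS event fraction equals `1 - censor_rate` (default 30%,
matching ~15 relapses in 51 patients over ~52 months median follow-up).

What the generator does **not** emulate: peptide-level structure, shared
peptides, batch blocks, heteroscedastic intensity-dependent CVs, or
correlated protein modules beyond the planted markers.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not performance on any real cohort.

## Preprocessing

1. **Presence filter** — keep proteins quantified in >= 80% of samples
   (inclusive threshold; configurable).
2. **Local least squares imputation** — for each incomplete protein, the
   `k = 10` fully observed proteins with highest |Pearson r| over the
   target's observed samples (computed on raw abundances) are donors; an
   affine least-squares fit predicts the missing cells.  Negative
   predictions are floored at the target's smallest observed value; targets
   with fewer than `k + 1` observed samples fall back to their observed
   mean.  Imputation runs before normalization and never alters observed
   cells.
3. **Stability ranking** — on natural-log data, a two-group variance
   decomposition in the NormFinder style: within each group, sample
   effects (row means of gene-centered data) are removed, per-protein
   residual variances estimated (with the `p/(p-1)` small-sample
   correction), and each protein's inter-group difference shrunk toward
   zero in proportion to its sampling variance.  Stability = mean over
   groups of |shrunken difference| + SE(group mean); lower is more stable.
   A transparent fallback (`method="simple"`) ranks by |group mean
   difference| + pooled SD.  The log base is irrelevant to the ranking
   (it rescales all stabilities equally).
4. **NSF normalization** — each of the top-K (default 4) stable proteins is
   divided by its cross-sample median; the geometric mean of those ratios
   in a sample is its normalization scaling factor, and all other proteins
   in the sample are divided by it.  The stable proteins are carried
   through unscaled by default and excluded from downstream analyses
   (configurable).

Two exactness caveats, verified algebraically and numerically: (i)
normalization from self-derived medians removes per-sample bias only up to
a single global scalar, because bias permutes which sample attains each
median — bit-exact removal holds when a fitted model's reference medians
are frozen (`fit_nsf(..., medians=...)`); (ii) refitting on a normalized
matrix returns NSF identically 1 only when the normalizers were themselves
scaled and the reference medians are reused — both forms are exposed and
tested.

A reference-correlation QC correlates per-protein median abundance (log
scale) against an external concentration map, with a one-sided permutation
p-value.

## Differential abundance and PLS-DA

The DAP test is the classical equal-variance two-sample Student's t-test on
log2 abundances (Welch behind a flag), with fold-change computed as the
ratio of group geometric means so |FC| > 2 is |log2FC| > 1 on the volcano
axis.  A protein is called at p < 0.05 **and** |FC| > 2; no multiplicity
correction enters the call (the discovery convention), but BH q-values are
reported alongside.

PLS-DA uses NIPALS partial least squares on the column-standardized log2
matrix with a dummy-coded response.  VIP_j =
sqrt(p * sum_a(w_aj^2 SSY_a) / sum_a SSY_a), so sum_j VIP_j^2 = p exactly —
a property test.  Explained-variance percentages are X-variance per
component (discriminant components need not be variance-ordered).

The confounder check stratifies by response and tests each candidate
marker across HR and HER2 status within strata; comparisons with < 2
samples per side or a constant factor are flagged degenerate rather than
tested.

## Feature selection and classifier evaluation

Backward elimination fits a random forest (default 10,000 trees, node size
5) on the current feature set, scores it by the AUC of out-of-bag class
probabilities, drops the least important feature, and repeats to a single
feature; the optimal subset is the smallest attaining the maximum OOB AUC
(ties favour fewer features).  The elimination ranking uses Gini (mean
decrease impurity) importance by default — the convention of AUC-oriented
RF elimination tools, and far cheaper at one feature drop per round — with
OOB-permutation importance available via `importance="permutation"`.

Probability of selection repeats the elimination on the training portions
of 50 iterations x 3-fold stratified splits; a feature's probability is the
fraction of runs in which it lands in the optimal subset, and features
above 0.5 form the panel.

Evaluation draws 100 stratified random trisections (train 2/3, validate
1/3).  Centering/scaling and all tuning use the training portion only: the
linear-SVM cost is tuned over {0.01, 0.1, 1, 10, 100} and the RF `mtry`
over 1..p by 3x3-fold CV on the training data.  Per-split validation ROC
curves are aggregated to a median AUC, a 2.5/97.5 percentile interval
(the "95% CI" of the median-AUC convention), and 25/50/75 sensitivity
quantile bands on a common 1-specificity grid.

## Survival analysis

Endpoints: DFS (any recurrence), OS (death from any cause), DMFS (distant
metastasis); death without prior recurrence censors DFS/DMFS.  Kaplan-Meier
estimation, the exposed two-group log-rank test, and Cox regression (Efron
tie handling, Wald CIs) are delegated to lifelines; median follow-up uses
the reverse-KM estimator.

The maxstat cutpoint search evaluates the standardized log-rank statistic
at every observed marker value whose split leaves >= 20% of samples in each
group, taking the maximizing |z| (ties -> smaller cutpoint).  Its
multiplicity-adjusted p-value uses the improved-Bonferroni approximation
for the supremum of a standardized Brownian bridge over [eps, 1-eps],

    p ~= 4 phi(b)/b + phi(b) (b - 1/b) * 2 log((1-eps)/eps),

with an exact permutation option.  The proteome-wide screen reports, per
protein and endpoint, the cutpoint, the raw log-rank p at that cutpoint
(the discovery convention; this quantity is anti-conservative by
construction) and the adjusted p (the calibrated quantity used in the null
tests), plus BH q-values.

Cox fits flag monotone likelihood: any binary covariate level with zero
events is reported as separated/unstable rather than as a finite hazard
ratio, and a diverging coefficient (|beta| > 15) is likewise marked.

## Numerical and test-profile choices

* Test and acceptance runs reduce `rf_ntree` to 200–1,000 and
  `probsel_iterations`/`eval_splits` proportionally; at these problem sizes
  the Monte-Carlo differences against the 10,000-tree defaults are within
  split-to-split noise.
* Null calibration of the classifier median AUC pools split AUCs over five
  independent null cohorts before taking the median, because one 51-sample
  cohort's chance structure is shared by every split drawn from it and the
  dataset-level spread of the single-cohort median is as large as the
  tolerance being checked.
* Zero-variance proteins in the t-test are reported as t = 0, p = 1
  (identical groups are evidence of no difference, not a 0/0 failure).
* Elimination/OOB seeds all derive from `RunConfig.seed` via
  `SeedSequence`; every randomized stage is reproducible and every CLI
  output records the seed.

## Known limitations

Competing-risk survival modelling, time-dependent covariates, peptide-level
inference, and pathway enrichment are out of scope.  The marker screen's
raw log-rank flags reproduce the discovery convention and should not be
read as calibrated significance — use the adjusted p or q columns for
that.  The generator's independence assumptions (no correlated protein
modules) make imputation and feature selection somewhat easier than on
real plasma data.
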