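# Methods

This note documents the statistical models implemented in `progsig`, the
choices made where a design was genuinely open, and what the synthetic data
do and do not establish.

## Cohort model (synthetic data)

`generate_cohort` simulates a two-group, three-time-point proteomic cohort.
All planted effects act on a latent standard-normal "expression" scale
`z`; measured concentrations are `x = b_j · exp(σ_log · z)` with a
per-analyte baseline `b_j ~ 10^U(1,4)` (blood) and σ_log = 0.3, giving the
positive, right-skewed distributions typical of aptamer and bead-array
assays. Because the transform is monotone and moderate, a shift of δ on the
z-scale corresponds closely to a standardised mean difference of δ on the
raw, autoscaled scale (≈ 1.4 at δ = 1.5; ≈ 2.5 at δ = 3).

Planted structure, all recorded in `GroundTruth`:

* **Signature.** `k_signature` analytes (allocated between compartments in
  proportion to panel sizes) shifted ±`effect_size`/2 per group with a
  random sign per analyte; the group difference is `effect_size` z-units.
  Default 1.5 — the source cohort reports no effect sizes, so this is a
  tunable, deliberately moderate choice (clear multivariate signal, weak
  univariate signal), not an estimate of any real cohort.
* **Correlation structure**, on the signature analytes, via latent factors
  (positive semi-definite at any dimension by construction). Non-progressors:
  one factor per block of ~3 analytes with loading √corr_strong → few,
  strong pairwise correlations (default |r| = 0.8). Progressors: 8 shared
  factors with per-factor loading √(corr_weak/8) → all pairs weakly
  correlated (default |r| = 0.3). This reproduces the "fewer but stronger
  correlations in non-progressors" contrast at the network stage.
* **Subgroups.** Progressors are split into `n_subgroups` (default 3)
  groups; each has a disjoint block of `subgroup_block_size` blood analytes
  elevated by `subgroup_effect` (default 3.0 z-units — blocks are meant to
  be visually distinct in a clustered heatmap). Blocks are disjoint from the
  signature so clustering heterogeneity can be tested independently of
  classification.
* **Temporal drift.** `n_drift_analytes` blood analytes drift linearly by
  `temporal_drift` (default 1.0) z-units per time-point index (0, 1, 2), in
  progressors only, with a random sign per analyte. Linear drift makes the
  week-48 centroid fall between weeks 0 and 80.
* **BAL assay artefacts.** Measured BAL values are the "biological" level
  multiplied by a per-sample total-protein factor (so total-protein
  normalisation is the correct inverse), then censored at the per-analyte
  empirical `lod_quantile` (default 10%); detection limits are recorded so
  ½-global-minimum imputation can be applied downstream.

What the generator does **not** emulate: within-subject correlation across
time points (each visit is an independent draw), plate/batch effects, and
aptamer cross-reactivity. Observations being independent across visits is a
deliberate choice: it makes the one-way ANOVA used at the trajectory stage
exactly nominal under the null, so type-I-error properties can be tested
sharply. Real longitudinal data would violate that independence, and the
one-way ANOVA (which mirrors the published procedure) would then be only an
approximation; a repeated-measures model is out of scope. Consequently,
passing tests demonstrate correctness of the *procedures* under the stated
generative model, not robustness to assay or longitudinal artefacts.

## Preprocessing

* ½-LOD imputation uses one global constant — half the smallest minimum
  detectable concentration across all analytes' standard curves — not a
  per-analyte value.
* Autoscaling uses the n−1 (sample) standard deviation. Scaling parameters
  estimated on calibration data are re-applied unchanged to held-out folds;
  no statistic is ever computed on test data. Zero-variance analytes raise
  by default, or are dropped with a logged warning (`on_constant="drop"`),
  the behaviour used inside pipelines.
* Reduced T²: a PCA retains the smallest number of components A reaching
  90% cumulative variance (configurable), capped at n−2 so the F-based
  limit exists. A sample's T² = Σ_a t²_a/λ_a is divided by
  T²₉₅ = A(n−1)(n+1)/(n(n−A))·F₀.₉₅(A, n−A); "reduced T² > 5" therefore
  means "five times outside the 95% ellipsoid". One algebraic caveat worth
  knowing: for a sample *inside* the fit, t²_a/λ_a ≤ n−1, so the reduced
  statistic is bounded by roughly n(n−A)/((n+1)F₀.₉₅); at n ≲ 30 even an
  arbitrarily extreme sample cannot reach 5. The iterative loop is
  therefore effective for cohort-sized n (≳ 50–100) and is a no-op on very
  small matrices. The loop removes exactly one sample per iteration,
  re-autoscales and refits, and aborts if it would remove more than half
  the samples.

## LASSO

Objective (1/2n)‖y − Xβ‖² + λ‖β‖₁, solved by cyclic coordinate descent
with residual updates, warm starts along the descending penalty grid and an
active-set inner loop; convergence when the largest coefficient change in a
sweep is below 1e−7. The grid has 100 points, geometric from
λ_max = max|Xᵀy|/n to 10⁻³λ_max. Binary outcomes are coded 0/1 and time
points 0/1/2; the fit is least-squares (not logistic), matching the standard
toolbox routine. CV folds are stratified by the response codes and
size-balanced to ±1; the fold assignment is seeded and recorded.

λ is chosen at the minimum CV mean squared error, with one refinement: the
**null-model guard**. The CV curve is an estimate with sampling error, and
under a signal-free response its argmin frequently sits just below λ_max,
retaining one spuriously correlated analyte — which then contaminates any
downstream test performed on the same data (a classic selection/inference
double dip). The guard compares the minimum against the intercept-only
model's CV MSE: if the null model is within one standard error (standard
deviation of per-fold means divided by √k) of the minimum, no signature is
declared (`EmptySignatureError`). Among non-null penalties the minimum-MSE
rule stands — this is *not* the 1-SE rule for choosing λ, only a guard on
claiming any signature at all. With a genuine signal the CV improvement
exceeds the SE by orders of magnitude and the guard never triggers.

Even with the guard, a finite dataset occasionally contains a chance feature
whose association with the response is real *within that sample* and
survives cross-validation; the downstream PCA/ANOVA on the same observations
then rejects. This residual selection bias is a property of the
select-then-test design itself (≈ 10% of null-group runs at 65 candidate
analytes and 75 observations) and should be kept in mind when interpreting
single-cohort temporal signatures.

## PLSDA

PLS1/NIPALS on the centred 0/1 coding with X-deflation per LV; weights unit
norm, scores mutually orthogonal. Predictions use b = W(PᵀW)⁻¹q; a sample
is assigned the class whose code is nearest the continuous prediction, with
exact midpoint ties going to the higher code. The LV count used for display
models is 2; inside cross-validation each training fold picks its LV count
(up to `n_lv_max`) by an inner 5-fold prediction-error minimum.

Orthogonalisation is a post-hoc rotation of the score space: an orthonormal
basis is built whose first direction is the fitted-value direction Tq, so
LV1 carries all class-predictive variation and later LVs are uncorrelated
with the class coding; loadings are recomputed as XᵀQ (exact because the
NIPALS residual is orthogonal to the score space), fitted values and
predictions are unchanged, and LV1 is sign-oriented so the class coded 0
(non-progressors) has a positive mean score. VIP scores are computed from
the NIPALS decomposition; Σ_j VIP²_j = p holds identically.

## Comparison statistics

Cochran's Q (χ², k−1 df) on the patients × models correct/incorrect matrix;
rows on which all models agree contribute nothing, and a fully concordant
matrix returns Q = 0, p = 1 with an explicit `no_discordance` flag (this is
the situation where the post hoc test "could not be applied"). McNemar post
hoc per pair: exact two-tailed binomial when b + c < 25, continuity-corrected
χ² (|b−c|−1)²/(b+c) otherwise; Bonferroni adjustment across pairs (the
published analysis says only "adjusted p"). The CV-accuracy comparison
treats the k per-fold accuracies as independent replicates in a one-way
ANOVA + Tukey HSD; folds share training data, so this is faithful to the
published procedure but anticonservative in principle.

## Structure and trajectories

Clustering: average linkage on 1 − r between sample profiles (signed r, the
heatmap convention; configurable), unsupervised, then *evaluated* against
the known labels by majority-mapping misclassification ("supervised" in the
sense of coloured/validated, not label-guided). Networks: all pairwise
Pearson correlations within a group over the signature analytes, edges kept
at raw p < 0.05 (no multiplicity correction, by design), hubs at degree ≥ 4,
group contrast via a pooled two-sample t-test on edge |r| values.

Trajectory PCA pools each group's observations across time points,
autoscales the signature columns, and fits an ordinary PCA; PC1 scores are
grouped by time point for the ANOVA + Tukey test and for Gaussian kernel
densities with the normal-reference bandwidth h = σ̂(4/(3n))^{1/5} on a
shared grid (± 4h beyond the score range; densities integrate to 1 within
1e−3). An empty temporal signature is reported as "no temporal difference"
rather than an error at the pipeline level.

## Numerical and testing notes

* The coordinate-descent kernel is JIT-compiled with numba when available
  and runs as pure Python otherwise (identical code path).
* Coefficients within 1e−9·λ of zero after soft-thresholding are treated as
  exact zeros when forming supports.
* Test problem sizes are scaled-down study analogues chosen for fast,
  repeated-seed property checks (e.g. 60–300 blood analytes instead of
  1,129); `scripts/acceptance.py` runs the pipeline once at the full study
  scale (59 subjects, 1,158 analytes, three time points).
* Degenerate inputs are flagged, not silently zeroed: undefined metrics set
  NaN plus a flag, zero-variance analytes are named, and "no discordance"
  is an explicit state.
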