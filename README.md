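# progsig

Cross-tissue-compartment and temporal proteomic signature discovery for
two-group longitudinal cohorts — built for the setting of idiopathic
pulmonary fibrosis (IPF), where "progressors" (death, transplant, acute
exacerbation, FVC drop > 10% or DLCO drop > 15% over 80 weeks of follow-up)
must be separated from non-progressors using a large blood proteomic panel
measured at weeks 0/48/80 and a small bronchoalveolar-lavage (BAL) cytokine
panel measured at baseline.

Single differentially expressed proteins rarely replicate as prognostic
biomarkers in IPF; the working hypothesis here is that progression is driven
by dysregulated *networks* of proteins spanning tissue compartments. The
package therefore implements a multivariate signature pipeline rather than
per-protein testing alone, together with a synthetic cohort generator that
plants known structure so every stage can be validated against ground truth.

## The methods at the core

* **Preprocessing.** Below-detection BAL values are imputed as ½ of the
  lowest minimum detectable concentration across all analytes, BAL
  concentrations are normalised to each sample's total protein, compartments
  are merged on shared subjects, and all analytes are autoscaled (mean 0,
  SD 1, n−1 denominator). "Negative driver" samples are removed iteratively:
  a PCA is fit, each sample's Hotelling T² over the retained components is
  divided by its 95% confidence limit
  T²₉₅ = A(n−1)(n+1)/(n(n−A)) · F₀.₉₅(A, n−A), and the worst sample with a
  reduced T² > 5 is dropped until none remains.
* **Signature selection.** The LASSO, min_β (1/2n)‖y − Xβ‖² + λ‖β‖₁, is
  solved by cyclic coordinate descent with soft-thresholding over a
  geometric grid of 100 penalties from λ_max down to 10⁻³λ_max; λ is chosen
  at the minimum 10-fold cross-validated MSE (scaling refit inside every
  training fold). Small fixed panels are selected instead by VIP score ≥ 1.
* **PLSDA.** PLS1/NIPALS regression on the 0/1 class coding, orthogonalised
  post hoc so latent variable 1 (LV1) carries the class-predictive variation
  (non-progressors score positive by convention). Variable importance in
  projection: VIP_j = √(p·Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a), with mean
  squared VIP equal to 1. Models are judged by calibration accuracy and
  seeded, stratified 10-fold cross-validation accuracy (fold sizes within
  ±1; 5–6 samples per fold at n = 59), plus ROC/AUC.
* **Model comparison.** Matched per-patient classification states are
  compared with Cochran's Q and pairwise McNemar post hoc tests (exact
  binomial below 25 discordant pairs, continuity-corrected χ² above;
  Bonferroni-adjusted). Per-fold CV accuracies are compared by one-way
  ANOVA with Tukey's HSD.
* **Structure.** Average-linkage hierarchical clustering of patients in
  Pearson correlation distance (1 − r), evaluated against the known labels;
  per-group correlation networks keeping only Pearson edges with p < 0.05,
  with hub proteins defined as nodes with ≥ 4 significant correlations, and
  a two-sample t-test contrasting edge strengths |r| between groups.
* **Trajectories.** Within each group, a LASSO with the ordinal time coding
  0/1/2 as response selects the temporal signature; a PCA over the pooled
  autoscaled observations gives per-time-point PC1 scores, tested by one-way
  ANOVA with Tukey's HSD and summarised by Gaussian kernel densities with
  the normal-reference bandwidth h = σ̂(4/3n)^{1/5}.

The synthetic generator (`progsig.synthetic`) emulates the study conditions:
log-normal positive concentrations, a planted cross-compartment signature,
three progressor subgroups with distinct overexpressed blocks, sparse-strong
(non-progressor) versus dense-weak (progressor) correlation structure via
latent factors, linear progressor-only temporal drift, and LOD-censored,
total-protein-scaled BAL values.

## Worked example

```python
import progsig as ps

cfg = ps.CohortConfig(n_prog=30, n_nonprog=20, p_blood=300, p_bal=29,
                      k_signature=20, effect_size=1.5, seed=11)
cohort = ps.generate_cohort(cfg)

bal = ps.normalize_total_protein(ps.impute_lod(cohort.bal_table, cohort.truth.bal_lods))
merged = ps.merge_compartments(cohort.blood_tables[0], bal)
merged, report = ps.prune_negative_drivers(merged)

y = (merged.groups == "progressor").astype(float).to_numpy()
signature = ps.lasso_cv(merged, y, k=10, seed=11)

panel = merged.subset_analytes(signature.analyte_ids)
labels = panel.groups.to_numpy()
model = ps.PLSDAClassifier(n_components=2, orthogonalized=True).fit(panel.values, labels)
cal = ps.classification_metrics(model.predict(panel.values), labels, positive_class="progressor")
cv = ps.cross_validate(panel.values, labels, k=10, seed=11)

nonp = ps.corr_network(merged, signature.analyte_ids, group="non_progressor")
prog = ps.corr_network(merged, signature.analyte_ids, group="progressor")
res = ps.compare_networks(nonp, prog)

sig_t = ps.temporal_signature(cohort.blood_tables, "progressor", seed=11)
anova = ps.pc1_anova(ps.trajectory_pca(cohort.blood_tables, sig_t, "progressor"))

hits = len(set(signature.analyte_ids) & set(cohort.truth.signature_analytes))
print(f"samples after reduced-T2 pruning: {merged.n_samples} (removed {len(report.removed_sample_ids)})")
print(f"LASSO signature: {len(signature)} analytes ({hits}/{len(cohort.truth.signature_analytes)} planted analytes recovered)")
print(f"PLSDA calibration accuracy: {100*cal.accuracy:.1f}%  CV accuracy: {100*cv.pooled_cv_accuracy:.1f}%")
print(f"sensitivity {100*cal.sensitivity:.0f}%, specificity {100*cal.specificity:.0f}%, "
      f"LV1 explains {100*model.explained_x_variance_[0]:.2f}% of X variance")
print(f"network edges: {res.edges_a} (non-progressor) vs {res.edges_b} (progressor); "
      f"mean |r| {res.mean_abs_r_a:.2f} vs {res.mean_abs_r_b:.2f} (t-test p = {res.p_value:.2g})")
print(f"temporal signature: {len(sig_t)} blood analytes; "
      f"PC1 ANOVA across weeks 0/48/80: p = {anova.p_value:.2g}")
```

printed (seed 11):

```
samples after reduced-T2 pruning: 50 (removed 0)
LASSO signature: 25 analytes (12/20 planted analytes recovered)
PLSDA calibration accuracy: 100.0%  CV accuracy: 100.0%
sensitivity 100%, specificity 100%, LV1 explains 25.30% of X variance
network edges: 23 (non-progressor) vs 27 (progressor); mean |r| 0.59 vs 0.44 (t-test p = 9.1e-06)
temporal signature: 19 blood analytes; PC1 ANOVA across weeks 0/48/80: p = 1e-43
```

Reading: the cross-compartment LASSO/PLSDA signature separates the two
groups perfectly in calibration and under 10-fold CV at this planted effect
size; the non-progressor network has fewer but significantly stronger
correlations than the progressor network; and the progressor-only temporal
drift produces a highly significant PC1 separation of the three collection
time points.

A command-line interface mirrors the library
(`progsig simulate / preprocess / volcano / select / plsda / network /
heatmap / compare / trajectory`); run `progsig --help`.

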