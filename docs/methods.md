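# Methods

`gdmetab` implements a complete first-trimester plasma metabolomics analysis
for predicting gestational diabetes mellitus (GDM): quality control and
preprocessing of multi-mode LC-MS abundance matrices, per-metabolite
association screening, random-forest biomarker panel discovery with
bootstrap stability selection and permutation validation, clinical risk-model
integration, and pathway over-representation analysis.  Because studies of
this design rarely deposit raw feature tables, the package ships a fully
specified synthetic cohort generator that reproduces the statistical
structure the analysis assumes, with ground truth for recovery testing.

## The synthetic cohort

The generator emulates a nested 1:1 case-control study: `n_cases = 50` women
who develop GDM at the 24–28-week oral glucose tolerance test (OGTT) and
`n_controls = 50` normoglycemic controls, group-matched on age and
pre-pregnancy BMI, profiled at < 16 weeks of gestation on three LC-MS
acquisition modes (polar; non-polar positive; non-polar negative — 151, 300
and 200 features by default, 651 in total).

**Abundance model.** Each metabolite *j* has a baseline
`mu_j ~ U(ln 10^3, ln 10^6)` and biological SD `sigma_j ~ U(0.2, 0.8)` on
the natural-log scale.  A biological sample in batch *b* is

```
ln x_ij = mu_j + delta_j * sigma_j * 1[case_i] + gamma_bj + d_bj * sigma_j * eps_ij
```

with `gamma_bj ~ N(0, 0.3)` additive and `d_bj = exp(N(0, 0.1))`
multiplicative batch distortions, and `eps ~ N(0,1)`.  Planted effects are
expressed in units of the metabolite's biological SD, so a "1-SD shift"
corresponds directly to a standardized logistic coefficient near 1.  By
default 49 metabolites carry true shifts drawn from ±(0.4, 1.1) (10%
negative), of which a "strong" subset of 8 is fixed at 1.0 SD — the planted
panel.  Batches are assigned round-robin over a case/control-interleaved
order, so batch and outcome are unconfounded unless the
`confound_batches_with_label` stress knob is set.

**Missingness.** Values below each metabolite's 10th percentile are censored
(MNAR, a limit-of-detection mechanism — exactly what half-minimum imputation
targets), after which 5% of the remaining cells drop out at random (MCAR).
The two rates add: the expected missing fraction is `q + (1-q)·m ≈ 14.5%`.

**Pooled QC injections.** Ten QC rows per dataset hold the pooled mean of
the biological samples perturbed by per-metabolite log-normal technical
noise whose CV is drawn from `U(0.05, 0.40)`.  The range deliberately
straddles the 20% RSD threshold, so the QC filter is genuinely exercised and
retains ≈ 43% of features — the attrition shape typical of untargeted runs
(e.g. 651 → ≈ 280).  Planted effect metabolites have their technical CV
capped at 0.15 (`effect_max_tech_cv`): a reported discovery panel is by
construction a set of well-measured, QC-passing features, and without this
coupling random QC attrition would delete half of any planted panel and no
recovery experiment would be meaningful.

**Clinical covariates** are drawn per arm from the cohort's baseline
characteristics (age 26/27 ± 2.5 y; BMI 22.8/23.8; waist 82/85 cm; family
history of type-2 diabetes 40%/54%; nulliparity 100%/68%; identical baseline
glycemia, separated OGTT glucose and follow-up HbA1c).  Age and BMI draws
are re-centered on their arm targets so the matched-design contrast (≈ 0.4
pooled SD) is not blurred by sampling noise.  Waist-to-height ratio is
derived from waist and a simulated height (155 ± 5.5 cm).

What the generator does *not* emulate: correlation structure among
metabolites (features are conditionally independent given batch), drift
within batches, annotation ambiguity, and real pathway topology.  Passing
recovery tests therefore demonstrate correctness of the statistical
machinery under the stated model, not field performance on real cohorts.

## Preprocessing

Stage order is fixed: QC RSD filter → missingness filter → half-minimum
imputation → `ln(1+x)` → ComBat → standardization → PCA → merge.  Boundary
semantics are strict inequalities: RSD > 20% nulls a feature (exactly 20% is
retained); > 40% missing drops it (exactly 40% is imputed).  Sample SD
(`ddof=1`) is used for both RSDs and standardization.  RSDs pool all QC
injections of a dataset.  A metabolite count ledger
(`input = nulled + dropped + retained`) is asserted on every run.

**ComBat.** The batch correction is the parametric empirical-Bayes
location/scale model: features are standardized against a design holding the
batch indicators and (by default) the case/control label as a protected
covariate; per-batch locations `gamma` and scales `delta²` are shrunk toward
normal / inverse-gamma priors estimated across the feature ensemble, with
the posterior equations iterated to convergence (tolerance 1e-4).  The
implementation is validated against `sva::ComBat` (R) to 1e-3 on a fixture.
Two degenerate cases are handled explicitly: a single batch returns the
input unchanged (there is nothing to correct, and the EB standardization
round-trip is not an exact identity), and when the protected label is
perfectly collinear with batch the joint design is rank-deficient — the
label effect is then estimated first, removed, the remainder corrected, and
the label effect restored.  This conservative policy preserves biological
signal at the cost of possibly retaining batch effect; it is the only
attribution consistent with "protecting" the label.

## Univariate screen

One logistic model per metabolite, `GDM ~ metabolite (+ covariates)`, on
standardized abundances; the coefficient is the log-odds change per 1 SD,
with Wald SEs, symmetric 95% CIs and two-sided p-values, BH-FDR adjusted
across metabolites.  Because each model has only 2–4 parameters, all
metabolites are fitted simultaneously by a batched Newton–Raphson (agreement
with `statsmodels.Logit` to 1e-6 is asserted in the tests); this makes
500-cohort null-calibration studies cheap.  Fits with (quasi-)separation or
constant features are flagged `converged=False` and excluded from the FDR
ranking.  Directions of association between metabolites and continuous
clinical variables (OGTT glucose, HbA1c, BMI, ...) use per-pair OLS with
BH-FDR within each variable; `up`/`down` at FDR < 0.05, else `no-change`.

## Panel discovery

Ten (configurable) stratified 70/30 iterations; within each training set,
`mtry`/`ntree` are tuned by stratified inner CV on AUC (defaults:
`mtry ∈ {√p, p/3, p/2}`, `ntree ∈ {250, 500, 1000}`; ties prefer the
smaller forest).  Features are re-ranked per iteration (permutation
importance on AUC by default; Gini optional; ties break on name order), and
the top-k sets (k = 1..10) are pooled over iterations into candidate panels
with duplicates merged.  Every candidate is validated by stratified
bootstrap (default B = 1000): refit on each resample, metrics on the
out-of-resample samples with the operating threshold at that replicate's
Youden point.  Out-of-resample rather than resubstitution evaluation is
deliberate — resubstitution would make the SDs trivially optimistic.  Within
each panel size, the lowest-AUC-SD candidate is the "stable" one; among
those, the highest bootstrap mean AUC wins (ties: smaller panel, then name
order).  The selected panel's headline ROC is a full-cohort logistic model
with a DeLong 95% CI (ridge fallback when the panel separates perfectly).
The permutation test reruns the split/fit/score procedure on label
shuffles and reports the add-one empirical p,
`(1 + #{null ≥ observed}) / (1 + P)`, never exactly zero.

The optimism gap between iterated split-test AUC and bootstrap AUC is a
real phenomenon at n = 100: the panel is chosen with full-cohort
information, so the split-test estimate is selection-biased upward, while
bootstrap refits train on resamples with duplicated observations and score
honest out-of-resample sets.  The test suite asserts the direction of the
gap over 20 seeded cohorts.

## Clinical models

Model 1a (age, pre-pregnancy BMI, family history, venous HbA1c), model 1b
(1a with waist-to-height ratio replacing BMI — published definitions of
these covariate sets vary, so both are plain tuples the caller can
override), and model 1c (the 1b covariates plus the metabolite panel).
All are logistic fits compared on identical complete-case samples with
in-sample (apparent) ROC/AUC and DeLong 95% CIs — matching the common
reporting style for small nested cohorts; a cross-validated ROC would be the
honest alternative and can be built from the `panels` module if needed.
Cohort description follows the usual form: mean ± SD with two-sample
t-tests for continuous variables; n (%) with chi-square (Fisher exact for
sparse 2×2) for categoricals.

## Enrichment

Over-representation of significant metabolites (as KEGG compound IDs)
against a local annotation table: one-sided Fisher exact p per pathway —
identically the hypergeometric upper tail `P[X ≥ k]`, which is asserted
against exhaustive enumeration for every 2×2 table with N ≤ 60 — with
BH-FDR across pathways.  The default background universe is the set of
measured metabolites that carry a compound ID.  No live database access:
annotations come from TSV files or the synthetic pathway generator (which
plants one guaranteed-enrichable pathway for recovery tests).

## Numerical and design choices

- Natural log throughout; monotone transforms do not affect rank-based
  downstream quantities.
- `+1` offset in the log transform; half-minimum imputation happens on the
  raw scale before it.
- Youden's J defines every operating threshold (bootstrap replicates use
  their own out-of-resample ROC; train/test evaluation carries the training
  threshold to the test set).
- All randomness flows from integer seeds; stage seeds are derived from the
  global seed with fixed offsets, so stages are independently reproducible
  and reruns are bit-identical.
- AUC CIs use DeLong's method; a bootstrap CI would also be defensible but
  DeLong is deterministic and cheap.

## Problem sizes used in the test and acceptance runs

The statistical suites run at sizes chosen once for a single-CPU session:

- FDR control: 500 null cohorts of 100 samples × 200 metabolites.
- Panel recovery: 20 seeded cohorts, 200 features (8 planted at 1 SD),
  2 split iterations, single-point grid with 256-tree ranking forests,
  B = 200 bootstrap replicates with 8-tree forests.
- Permutation calibration: 200 repeats of P = 99 on null data (80 × 5),
  50/50 split, 8-tree forests; power: 100 runs of P = 199 on a planted
  8-feature panel at n = 100.
- Optimism gap: 20 seeded cohorts, ranking on the full cohort, 10 split
  iterations, B = 100.
- `scripts/acceptance.py`: the full 651-feature default cohort with 5 split
  iterations, the default tuning grid, B = 200, P = 199 and 16-tree
  bootstrap forests.

Library defaults remain the full-size procedure (10 iterations, 10-fold
inner CV, B = 1000, P = 1000).

## Known limitations

- Feature independence in the generator understates the multiplicity burden
  of correlated lipid families and makes panel redundancy invisible.
- The apparent (in-sample) model-comparison AUCs are optimistic by design;
  they are reported because that is the convention being mirrored, and the
  bootstrap machinery quantifies the gap.
- The enrichment results depend entirely on the annotation table supplied;
  with synthetic annotations only the planted pathway is meaningful.
- Half-minimum imputation biases low-abundance group contrasts; no
  model-based imputation alternative is provided.
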