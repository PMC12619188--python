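# gdmetab

**First-trimester plasma metabolomics for early prediction of gestational
diabetes mellitus (GDM).**

GDM is usually diagnosed by an oral glucose tolerance test (OGTT) at 24–28
weeks of pregnancy — too late for early intervention.  Untargeted LC-MS
metabolomics of early-pregnancy (< 16 weeks) plasma can reveal lipid and
amino-acid signatures that precede hyperglycemia.  `gdmetab` is a tested,
reusable implementation of the full analysis such a study requires, aimed at
metabolomics analysts and biostatisticians:

1. **QC / preprocessing** of three acquisition-mode abundance matrices
   (polar, non-polar positive, non-polar negative): pooled-QC RSD filtering
   (features with RSD > 20% nulled), missingness filtering (> 40% dropped),
   half-minimum imputation, `ln(1+x)`, ComBat empirical-Bayes batch
   correction, standardization, PCA, and an inner-join merge on
   (batch, sample) IDs.
2. **Univariate screen**: per-metabolite logistic regression
   (GDM ~ metabolite), log-odds per 1 SD with Wald 95% CIs,
   Benjamini–Hochberg FDR; volcano-plot and clinical-variable direction
   tables.
3. **Panel discovery**: random forests over iterated stratified 70/30
   splits with inner-CV hyperparameter tuning, importance-ranked top-k
   candidate panels (k = 1..10), stratified bootstrap validation (refit per
   resample, out-of-resample metrics at the Youden point), stability
   selection (lowest AUC-SD per size, then highest AUC), and a
   label-permutation test with add-one p-values.
4. **Clinical models**: conventional-risk logistic models (age, BMI or
   waist-to-height ratio, family history of diabetes, venous HbA1c), the
   metabolite panel, and the integrated model, compared by in-sample
   ROC/AUC with DeLong 95% CIs; baseline-characteristics tables.
5. **Pathway enrichment**: one-sided Fisher exact (hypergeometric upper
   tail) over-representation of significant metabolites against local
   KEGG-style annotation tables, BH-FDR adjusted.

Because raw feature tables for such cohorts are typically not deposited, the
package includes a first-class **synthetic cohort generator** — a seeded
50-case / 50-control nested case-control emulation with batch effects,
MNAR/MCAR missingness, pooled-QC replicates of controlled technical CV,
planted effect metabolites, and clinical covariates calibrated to published
baseline characteristics — plus the ground truth needed for recovery tests.
The model and its parameters are documented in [docs/methods.md](docs/methods.md).

## Worked example

```python
from gdmetab import (SyntheticConfig, generate_cohort, preprocess_dataset,
                     merge_datasets, fit_metabolite_logistic)

matrices, clinical, truth = generate_cohort(SyntheticConfig(seed=1))
processed = [preprocess_dataset(m)[0] for m in matrices.values()]
merged = merge_datasets(*processed)
labels = clinical.loc[merged.values.index, "gdm"]

assoc = fit_metabolite_logistic(merged.values, labels)
sig = assoc[(assoc.fdr_p < 0.05) & assoc.converged]
print(len(assoc), "metabolites tested,", len(sig), "significant at FDR<0.05")
```

prints

```
321 metabolites tested, 23 significant at FDR<0.05
```

— of 651 simulated features, 321 survive QC (the RSD filter removes
features whose pooled-QC technical CV exceeds 20%, the missingness filter
the rest), and 23 reach FDR significance; each significant row carries the
standardized log-odds estimate, its 95% CI and the FDR-adjusted p-value.
The `examples/` directory continues from here, one script per capability
(simulation, preprocessing, univariate screen, panel discovery, clinical
models, enrichment, and the one-call pipeline); each prints the quantities
it computes and a line on how to read them.  The end-to-end entry point is

```python
from gdmetab import RunConfig, run_pipeline
report = run_pipeline(RunConfig(synthetic=SyntheticConfig(seed=1), seed=1))
```

and a thin CLI wraps it: `gdmetab simulate --outdir cohort/` writes a
synthetic cohort as delimited text, `gdmetab run --seed 1 --outdir out/`
runs the pipeline and persists every stage table.

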