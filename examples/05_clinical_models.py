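"""Conventional-risk vs metabolite-panel vs integrated GDM prediction.

Model 1a: age, pre-pregnancy BMI, family history, venous HbA1c.
Model 1b: as 1a with waist-to-height ratio in place of BMI.
Model 1c: the 1b covariates plus the metabolite panel (integrated model).
All AUCs are in-sample with DeLong 95% CIs on identical complete cases.
"""

from gdmetab import (
    ModelSpec,
    SyntheticConfig,
    compare_models,
    generate_cohort,
    merge_datasets,
    preprocess_dataset,
    summarize_tableone,
)

matrices, clinical, truth = generate_cohort(SyntheticConfig(seed=1))
merged = merge_datasets(*[preprocess_dataset(m)[0] for m in matrices.values()])
panel = tuple(m for m in truth.strong_metabolites if m in merged.values.columns)

specs = [ModelSpec.model_1a(), ModelSpec.model_1b(), ModelSpec.model_1c(panel)]
print(compare_models(specs, clinical, merged.values).round(3).to_string())
print("\nBaseline characteristics (GDM=1 vs NGT=0):")
table1 = summarize_tableone(
    clinical,
    continuous=["age", "bmi", "ogtt_2h", "hba1c_followup"],
    categorical=["family_history"],
)
print(table1.to_string())
# Expected pattern: the clinical-only models sit near chance on a matched
# cohort, the metabolite panel carries the discrimination, and the
# integrated model is at least as good in-sample.
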