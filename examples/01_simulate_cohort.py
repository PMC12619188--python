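"""Generate a synthetic 50-case / 50-control metabolomics cohort.

The generator emulates a nested case-control study with three LC-MS
acquisition modes, pooled-QC injections, batch effects, MNAR/MCAR
missingness and a planted panel of truly shifted metabolites.
"""

from gdmetab import SyntheticConfig, generate_cohort

config = SyntheticConfig(seed=1)
matrices, clinical, truth = generate_cohort(config)

for tag, m in matrices.items():
    missing = m.biological_values().isna().mean().mean()
    print(
        f"{tag:13s}: {m.n_samples} rows ({int(m.is_qc.sum())} QC) x "
        f"{m.n_metabolites} metabolites, {missing:.1%} missing"
    )
print(f"clinical table: {clinical.shape[0]} participants, "
      f"{int(clinical.gdm.sum())} GDM cases")
print(f"planted effect metabolites: {len(truth.effect_metabolites)} "
      f"(strong panel of {len(truth.strong_metabolites)} at 1-SD shift)")
# The three matrices plus the clinical table are the inputs every later
# stage consumes; `truth` records what was planted for recovery checks.
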