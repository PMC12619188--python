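"""One-call end-to-end run: simulate -> preprocess -> associate -> panel ->
clinical models -> permutation test -> enrichment -> report.

Sizes are scaled down so the example finishes in about a minute; the same
entry point drives the full-size analysis (see scripts/acceptance.py).
"""

import numpy as np

from gdmetab import RFGrid, RunConfig, SplitScheme, SyntheticConfig, run_pipeline

config = RunConfig(
    synthetic=SyntheticConfig(
        n_metabolites_per_dataset=(60, 8, 8),
        effect_set_size=12,
        strong_subset_size=8,
        kegg_annotation_fraction=1.0,
        seed=2,
    ),
    scheme=SplitScheme(n_iterations=3, inner_folds=5, base_seed=2),
    grid=RFGrid(mtry=(3,), ntree=(128,)),
    importance="gini",
    bootstrap_B=100,
    permutation_P=99,
    boot_ntree=16,
    seed=2,
)
report = run_pipeline(config)

print("QC ledger:", report.qc_ledger)
print(f"significant metabolites: {report.n_significant}")
print(f"final panel ({len(report.final_panel)}): {', '.join(report.final_panel)}")
fp = report.final_panel_metrics
print(f"  mean test AUC {fp['mean_test_auc']:.3f} | "
      f"bootstrap AUC {fp['bootstrap_mean']['auc']:.3f} "
      f"+/- {fp['bootstrap_sd']['auc']:.3f}")
print(f"panel logistic AUC {report.panel_roc['auc']:.3f} "
      f"[{report.panel_roc['ci_low']:.3f}, {report.panel_roc['ci_high']:.3f}]")
print(report.model_comparison.round(3).to_string())
print(f"permutation p = {report.permutation_p:.4g} "
      f"(null mean AUC {np.mean(report.permutation_null):.3f})")
if report.enrichment is not None:
    top = report.enrichment.iloc[0]
    print(f"top pathway: {top.pathway_name} (FDR p = {top.fdr_p:.2e})")
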