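"""End-to-end seeded runs: simulate/load -> preprocess -> associate ->
panel discovery -> clinical models -> enrichment -> report.

A :class:`RunConfig` either points at on-disk inputs (three abundance
matrices with metadata sidecars, a clinical table, a pathway-annotation TSV)
or carries a :class:`~gdmetab.synthetic.SyntheticConfig` block; exactly one
of the two must be present.  One global seed drives every stage through
fixed offsets, so stages are independently reproducible and a rerun with the
same config reproduces all numbers exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import associations, clinical as clinical_mod, enrichment as enrich_mod
from . import panels as panels_mod
from .matrix import AbundanceMatrix, DATASET_TAGS
from .preprocess import PreprocessConfig, merge_datasets, preprocess_dataset
from .synthetic import SyntheticConfig, generate_cohort, generate_pathway_db

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (see module docstring)."""

    synthetic: SyntheticConfig | None = None
    input_dir: str | None = None           # holds <tag>_values/_samples/_metabolites.tsv
    clinical_path: str | None = None
    annotations_path: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    scheme: panels_mod.SplitScheme | None = None
    grid: panels_mod.RFGrid | None = None
    importance: str = "permutation"
    max_panel_size: int = 10
    bootstrap_B: int = 1000
    permutation_P: int = 1000
    boot_ntree: int | None = None
    alpha: float = 0.05
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_dir is None):
            raise ValueError("exactly one of synthetic config or input paths required")
        if self.input_dir is not None and self.clinical_path is None:
            raise ValueError("file-based runs need a clinical table path")


@dataclass
class RunReport:
    seed: int
    config_hash: str
    qc_ledger: dict[str, dict[str, int]]
    associations: pd.DataFrame
    n_significant: int
    panel_table: pd.DataFrame
    final_panel: tuple[str, ...]
    final_panel_metrics: dict
    panel_roc: dict
    model_comparison: pd.DataFrame
    permutation_p: float
    permutation_null: np.ndarray
    enrichment: pd.DataFrame | None
    tableone: pd.DataFrame

    def save(self, outdir: str | Path) -> None:
        """Persist every section as delimited text / JSON under ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.associations.to_csv(out / "associations.tsv", sep="\t")
        self.panel_table.to_csv(out / "panel_metrics.tsv", sep="\t", index=False)
        self.model_comparison.to_csv(out / "model_comparison.tsv", sep="\t")
        self.tableone.to_csv(out / "tableone.tsv", sep="\t")
        if self.enrichment is not None:
            self.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        np.savetxt(out / "permutation_null.txt", self.permutation_null, header=f"seed={self.seed}")
        summary = {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "qc_ledger": self.qc_ledger,
            "n_significant": self.n_significant,
            "final_panel": list(self.final_panel),
            "final_panel_metrics": self.final_panel_metrics,
            "panel_roc": {k: v for k, v in self.panel_roc.items() if k != "coefficients"},
            "permutation_p": self.permutation_p,
        }
        (out / "report.json").write_text(json.dumps(summary, indent=1))


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    payload = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        synth = config.synthetic
        matrices, clin, truth = generate_cohort(synth)
        return matrices, clin, truth
    base = Path(config.input_dir)
    matrices = {tag: AbundanceMatrix.from_dir(base, prefix=tag) for tag in DATASET_TAGS}
    clin = pd.read_csv(config.clinical_path, sep="\t", index_col=0)
    return matrices, clin, None


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis and return (and optionally persist) a report."""
    seed = config.seed
    matrices, clin, truth = _load_inputs(config)

    # --- preprocessing, per acquisition mode, then merge ------------------
    processed, ledgers = {}, {}
    for tag, m in matrices.items():
        pm, report = preprocess_dataset(m, config.preprocess)
        processed[tag] = pm
        ledgers[tag] = dict(report.counts)
        if not report.ledger_consistent():
            raise RuntimeError(f"[preprocess:{tag}] metabolite ledger is inconsistent")
    merged = merge_datasets(*processed.values())
    logger.info("merged matrix: %d samples x %d metabolites", *merged.values.shape)

    labels = clin.loc[merged.values.index, "gdm"].astype(int)

    # --- univariate screen ------------------------------------------------
    assoc = associations.fit_metabolite_logistic(merged.values, labels)
    sig = assoc[(assoc["fdr_p"] < config.alpha) & assoc["converged"]]
    sig = sig.sort_values("fdr_p", kind="stable")
    logger.info("univariate screen: %d significant metabolites", len(sig))
    if len(sig) < 2:
        raise RuntimeError("[associate] fewer than 2 significant metabolites; cannot build panels")

    # --- panel discovery on the significant features ----------------------
    Xsig = merged.values[sig.index]
    scheme = config.scheme or panels_mod.SplitScheme(base_seed=seed)
    disc = panels_mod.discover_panel(
        Xsig,
        labels.to_numpy(),
        scheme=scheme,
        grid=config.grid,
        max_panel_size=config.max_panel_size,
        B=config.bootstrap_B,
        importance=config.importance,
        boot_ntree=config.boot_ntree,
        seed=seed,
    )
    final = disc.final
    panel_roc = panels_mod.panel_logistic_roc(merged.values, labels, final.members)

    # --- permutation test of the panel pipeline ---------------------------
    ntree_b = config.boot_ntree or disc.tuned_params[0]["ntree"]
    Xp = Xsig[list(final.members)]

    def metric_fn(perm_labels, s):
        aucs = []
        for it in range(scheme.n_iterations):
            tr, te = panels_mod.stratified_split(perm_labels, scheme, it)
            try:
                aucs.append(
                    panels_mod.evaluate_on_test(
                        Xp, perm_labels, final.members, tr, te, ntree=ntree_b, seed=s
                    )["auc"]
                )
            except ValueError:
                continue
        return float(np.mean(aucs)) if aucs else 0.5

    perm = panels_mod.permutation_test(
        metric_fn, labels.to_numpy(), P=config.permutation_P, seed=seed
    )

    # --- clinical models --------------------------------------------------
    specs = [
        clinical_mod.ModelSpec.model_1a(),
        clinical_mod.ModelSpec.model_1b(),
        clinical_mod.ModelSpec.model_1c(final.members),
    ]
    comparison = clinical_mod.compare_models(specs, clin, merged.values)
    tableone = clinical_mod.summarize_tableone(
        clin.drop(columns=[c for c in ("height",) if c in clin]), group="gdm"
    )

    # --- enrichment -------------------------------------------------------
    enr = None
    kegg = merged.metabolite_meta["kegg_id"]
    universe = sorted(kegg.dropna().unique())
    sig_ids = sorted(kegg.loc[[m for m in sig.index if m in kegg.index]].dropna().unique())
    if universe and sig_ids:
        if config.annotations_path:
            annotations = enrich_mod.load_annotations(config.annotations_path)
        else:
            planted = sorted(
                kegg.loc[[m for m in (truth.effect_metabolites if truth else []) if m in kegg.index]]
                .dropna()
                .unique()
            ) or None
            annotations = generate_pathway_db(
                30, universe, planted_pathway=planted, seed=seed
            )
        enr = enrich_mod.fisher_enrichment(sig_ids, universe, annotations, alpha=config.alpha)

    report = RunReport(
        seed=seed,
        config_hash=_config_hash(config),
        qc_ledger=ledgers,
        associations=assoc,
        n_significant=len(sig),
        panel_table=disc.table(),
        final_panel=final.members,
        final_panel_metrics={
            "mean_test_auc": float(np.mean(final.test_aucs)),
            "bootstrap_mean": final.bootstrap_mean,
            "bootstrap_sd": final.bootstrap_sd,
        },
        panel_roc=panel_roc,
        model_comparison=comparison,
        permutation_p=perm.p_value,
        permutation_null=perm.null_values,
        enrichment=enr,
        tableone=tableone,
    )
    if config.outdir:
        report.save(config.outdir)
    return report
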