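"""Seeded synthetic GDM metabolomics cohorts with known ground truth.

The generator emulates the data structure of a nested 50-case / 50-control
first-trimester metabolomics study: three LC-MS abundance matrices (polar,
non-polar positive mode, non-polar negative mode) with pooled-QC technical
replicates, batch effects, limit-of-detection (MNAR) plus completely-random
(MCAR) missingness, a subset of metabolites truly shifted in cases, and a
clinical covariate table calibrated to the cohort's published baseline
characteristics.  Every random draw flows from a single integer seed, so a
configuration reproduces bit-identically.

The abundance model is log-normal per metabolite: on the natural-log scale a
biological sample is ``mu_j + batch additive offset + batch scale * eps``,
and case status adds ``shift_j * sigma_j`` for effect metabolites, i.e. the
planted shifts are expressed in units of the metabolite's biological SD so
that downstream standardized effect estimates are directly comparable to the
planted magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .matrix import AbundanceMatrix, DATASET_TAGS

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_pathway_db",
    "default_clinical_params",
]


def default_clinical_params() -> dict:
    """Per-arm clinical distributions (control, case) on their natural units.

    Continuous variables are (mean, SD) pairs; binaries are event
    proportions; socioeconomic class is a 3-level probability vector
    (lower, middle, upper).  Values are calibrated to a South-Indian
    early-pregnancy GDM nested case-control cohort: cases and controls are
    group-matched on age and pre-pregnancy BMI, glycemia separates only at
    the 24-28 week OGTT.
    """
    return {
        "age": {"control": (26.0, 2.4), "case": (27.0, 2.6)},
        "gestational_age": {"control": (10.0, 3.1), "case": (10.5, 3.1)},
        "prepreg_weight": {"control": (55.3, 7.6), "case": (56.4, 8.6)},
        "bmi": {"control": (22.8, 2.1), "case": (23.8, 2.9)},
        "waist": {"control": (82.0, 7.5), "case": (85.0, 8.2)},
        "height": {"control": (155.0, 5.5), "case": (155.0, 5.5)},
        "sbp": {"control": (101.0, 10.4), "case": (104.0, 10.0)},
        "dbp": {"control": (66.0, 8.0), "case": (68.0, 7.5)},
        "fpg": {"control": (83.0, 5.2), "case": (83.0, 3.9)},
        "hba1c_baseline": {"control": (5.02, 0.3), "case": (5.02, 0.3)},
        "ogtt_fasting": {"control": (80.5, 5.7), "case": (85.0, 6.5)},
        "ogtt_1h": {"control": (129.0, 23.3), "case": (179.0, 28.7)},
        "ogtt_2h": {"control": (112.0, 16.8), "case": (148.0, 28.6)},
        "hba1c_followup": {"control": (4.76, 0.3), "case": (4.92, 0.3)},
        "family_history": {"control": 0.40, "case": 0.54},
        "ses": {"control": (0.08, 0.64, 0.28), "case": (0.20, 0.56, 0.24)},
        "nulliparous": {"control": 1.00, "case": 0.68},
    }


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic cohort; defaults are the emulated study design.

    ``n_metabolites_per_dataset`` defaults to 651 features split across the
    three acquisition modes, of which ``effect_set_size`` carry a true
    case-control shift and ``strong_subset_size`` of those form the planted
    "panel" with a 1-SD shift.  ``tech_cv_range`` is the uniform range of
    per-metabolite technical coefficients of variation used for the pooled-QC
    replicates; the default (0.05, 0.40) straddles the 20% RSD pass threshold
    so roughly 43% of features survive QC, matching the attrition shape of
    real untargeted runs.
    """

    n_cases: int = 50
    n_controls: int = 50
    n_metabolites_per_dataset: tuple[int, int, int] = (151, 300, 200)
    n_batches: int = 3
    n_qc_injections: int = 10
    effect_set_size: int = 49
    strong_subset_size: int = 8
    effect_log_mean_shift: tuple[float, float] = (0.4, 1.1)
    strong_shift: float = 1.0
    negative_effect_fraction: float = 0.1
    batch_additive_sd: float = 0.3
    batch_scale_sd: float = 0.1
    mcar_rate: float = 0.05
    mnar_quantile: float = 0.10
    tech_cv_range: tuple[float, float] = (0.05, 0.40)
    effect_max_tech_cv: float = 0.15
    kegg_annotation_fraction: float = 0.6
    confound_batches_with_label: bool = False
    clinical_params: dict = field(default_factory=default_clinical_params)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_cases,
            self.n_controls,
            *self.n_metabolites_per_dataset,
            self.n_batches,
            self.n_qc_injections,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all sample/metabolite/batch/QC counts must be positive")
        if not (0 <= self.mcar_rate < 1):
            raise ValueError("mcar_rate must lie in [0, 1)")
        if not (0 <= self.mnar_quantile < 1):
            raise ValueError("mnar_quantile must lie in [0, 1)")
        total = sum(self.n_metabolites_per_dataset)
        if not (self.strong_subset_size <= self.effect_set_size <= total):
            raise ValueError(
                "need strong_subset_size <= effect_set_size <= total metabolites"
            )
        lo, hi = self.tech_cv_range
        if not (0 < lo <= hi):
            raise ValueError("tech_cv_range must be a positive interval")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    effect_metabolites: list[str]
    strong_metabolites: list[str]
    true_log_shift: dict[str, float]
    true_batch_offsets: dict[str, dict[str, float]]
    true_technical_cv: dict[str, float]
    clinical_effects: dict[str, dict]

    def __post_init__(self) -> None:
        if not set(self.strong_metabolites) <= set(self.effect_metabolites):
            raise ValueError("strong metabolites must be a subset of effect metabolites")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))


# ---------------------------------------------------------------------------
# cohort generation


def _lipid_class(dataset: str, rng: np.random.Generator) -> str:
    if dataset == "polar":
        return rng.choice(["amino_acid", "organic_acid", "sugar", "vitamin"])
    return rng.choice(["PC", "PE", "PS", "PG", "SM", "TAG", "DAG", "LPC", "HexCer"])


def _draw_arm(rng, spec, n):
    """Draw one clinical variable for one arm."""
    if isinstance(spec, tuple) and len(spec) == 2:
        mean, sd = spec
        return rng.normal(mean, sd, size=n)
    if isinstance(spec, tuple):  # categorical probability vector
        return rng.choice(len(spec), size=n, p=spec)
    return (rng.random(n) < spec).astype(int)  # binary proportion


def _clinical_table(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    params = config.clinical_params
    n_case, n_ctrl = config.n_cases, config.n_controls
    rows = {}
    for var, arms in params.items():
        ctrl = _draw_arm(rng, arms["control"], n_ctrl)
        case = _draw_arm(rng, arms["case"], n_case)
        if var in ("age", "bmi"):
            # group matching: recenter each arm's draws on its target mean so
            # the matched-design contrast is not blurred by sampling noise
            ctrl = ctrl - ctrl.mean() + arms["control"][0]
            case = case - case.mean() + arms["case"][0]
        rows[var] = np.concatenate([ctrl, case])
    df = pd.DataFrame(rows)
    df["height"] = np.clip(df["height"], 140.0, 180.0)
    df["whtr"] = df["waist"] / df["height"]
    df["ses"] = df["ses"].map({0: "lower", 1: "middle", 2: "upper"})
    df["gdm"] = np.concatenate([np.zeros(n_ctrl, int), np.ones(n_case, int)])
    df.index = [f"S{i:03d}" for i in range(len(df))]
    df.index.name = "sample_id"
    # physical-range guards
    for col in ("age", "bmi", "fpg", "ogtt_fasting", "ogtt_1h", "ogtt_2h"):
        df[col] = np.clip(df[col], 1.0, None)
    return df


def _generate_dataset(
    dataset: str,
    n_met: int,
    met_offset: int,
    clinical: pd.DataFrame,
    config: SyntheticConfig,
    shifts: dict[str, float],
    rng: np.random.Generator,
) -> tuple[AbundanceMatrix, dict[str, dict[str, float]], dict[str, float]]:
    names = [f"{dataset}_M{met_offset + j:04d}" for j in range(n_met)]
    n_bio = len(clinical)
    labels = clinical["gdm"].to_numpy()

    # per-metabolite baseline on the ln scale
    mu = rng.uniform(np.log(1e3), np.log(1e6), size=n_met)
    sigma = rng.uniform(0.2, 0.8, size=n_met)

    # batch assignment: round-robin over the case/control-interleaved order
    # keeps batches balanced w.r.t. label; the confounding knob assigns
    # contiguous blocks instead (label and batch then correlate).
    order = np.argsort(np.argsort(-labels, kind="stable"), kind="stable")
    if config.confound_batches_with_label:
        batch = np.repeat(
            np.arange(config.n_batches), int(np.ceil(n_bio / config.n_batches))
        )[:n_bio]
    else:
        interleave = np.empty(n_bio, dtype=int)
        interleave[np.argsort(-labels, kind="stable")] = np.arange(n_bio)
        batch = interleave % config.n_batches
    del order

    gamma = rng.normal(0.0, config.batch_additive_sd, size=(config.n_batches, n_met))
    log_delta = rng.normal(0.0, config.batch_scale_sd, size=(config.n_batches, n_met))
    delta = np.exp(log_delta)

    shift_vec = np.array([shifts.get(m, 0.0) for m in names])
    eps = rng.normal(size=(n_bio, n_met))
    log_x = (
        mu[None, :]
        + shift_vec[None, :] * sigma[None, :] * labels[:, None]
        + gamma[batch]
        + delta[batch] * sigma[None, :] * eps
    )
    x = np.exp(log_x)

    # MNAR: left-censor below the metabolite's mnar_quantile, then MCAR on
    # the remaining observed cells so the two rates add.
    if config.mnar_quantile > 0:
        cut = np.quantile(x, config.mnar_quantile, axis=0)
        x = np.where(x < cut[None, :], np.nan, x)
    if config.mcar_rate > 0:
        drop = rng.random(x.shape) < config.mcar_rate
        x = np.where(drop & ~np.isnan(x), np.nan, x)

    # pooled QC injections: pool mean of biological samples perturbed with a
    # per-metabolite technical CV (log-normal multiplicative noise whose CV
    # equals the drawn value).
    cv = rng.uniform(*config.tech_cv_range, size=n_met)
    # planted effect metabolites are well-measured by construction (a
    # discovery panel necessarily comes from QC-passing features): rescale
    # their technical CVs into (lo, effect_max_tech_cv)
    lo_cv, hi_cv = config.tech_cv_range
    cap = min(hi_cv, config.effect_max_tech_cv)
    if cap > lo_cv and hi_cv > lo_cv:
        is_effect = shift_vec != 0
        cv = np.where(
            is_effect, lo_cv + (cv - lo_cv) * (cap - lo_cv) / (hi_cv - lo_cv), cv
        )
    pool = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    pool = np.where(np.isnan(pool), np.exp(mu), pool)
    s_ln = np.sqrt(np.log1p(cv**2))
    qc_noise = rng.normal(size=(config.n_qc_injections, n_met))
    qc = pool[None, :] * np.exp(s_ln[None, :] * qc_noise - 0.5 * s_ln[None, :] ** 2)

    values = pd.DataFrame(
        np.vstack([x, qc]),
        index=list(clinical.index) + [f"QC_{dataset}_{i:02d}" for i in range(config.n_qc_injections)],
        columns=names,
    )
    sample_meta = pd.DataFrame(
        {
            "batch_id": [f"B{b + 1}" for b in batch]
            + [f"B{(i % config.n_batches) + 1}" for i in range(config.n_qc_injections)],
            "is_qc": [False] * n_bio + [True] * config.n_qc_injections,
            "label": list(labels.astype(float)) + [np.nan] * config.n_qc_injections,
        },
        index=values.index,
    )
    n_annot = int(round(config.kegg_annotation_fraction * n_met))
    annotated = rng.choice(n_met, size=n_annot, replace=False)
    kegg = np.full(n_met, np.nan, dtype=object)
    for j in annotated:
        kegg[j] = f"C{met_offset + j + 10000:05d}"
    metabolite_meta = pd.DataFrame(
        {
            "dataset": dataset,
            "lipid_class": [_lipid_class(dataset, rng) for _ in names],
            "kegg_id": kegg,
        },
        index=names,
    )
    matrix = AbundanceMatrix(values, sample_meta, metabolite_meta)
    batch_offsets = {
        f"B{b + 1}": {names[j]: float(gamma[b, j]) for j in range(n_met)}
        for b in range(config.n_batches)
    }
    true_cv = {names[j]: float(cv[j]) for j in range(n_met)}
    return matrix, batch_offsets, true_cv


def generate_cohort(
    config: SyntheticConfig | None = None,
) -> tuple[dict[str, AbundanceMatrix], pd.DataFrame, GroundTruth]:
    """Generate the three abundance matrices, the clinical table and truth.

    Returns
    -------
    matrices
        ``{"polar": ..., "nonpolar_pos": ..., "nonpolar_neg": ...}``; each
        holds the biological samples plus that dataset's pooled-QC rows.
    clinical
        One row per participant (sample_id index) with the baseline and
        OGTT-visit covariates and the binary ``gdm`` outcome.
    truth
        Planted effect sets, per-metabolite shifts, batch offsets and
        technical CVs.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng([config.seed, 0x5EED])

    clinical = _clinical_table(config, rng)

    # choose effect metabolites across the pooled feature space
    all_names: list[str] = []
    offsets = {}
    for tag, n_met in zip(DATASET_TAGS, config.n_metabolites_per_dataset):
        offsets[tag] = len(all_names)
        all_names += [f"{tag}_M{len(all_names) + j:04d}" for j in range(n_met)]
    effect_idx = rng.choice(len(all_names), size=config.effect_set_size, replace=False)
    effect_names = [all_names[i] for i in sorted(effect_idx)]
    strong_names = sorted(
        str(m) for m in rng.choice(effect_names, size=config.strong_subset_size, replace=False)
    )
    lo, hi = config.effect_log_mean_shift
    shifts = {}
    for m in effect_names:
        mag = config.strong_shift if m in strong_names else rng.uniform(lo, hi)
        sign = -1.0 if rng.random() < config.negative_effect_fraction else 1.0
        shifts[m] = float(sign * mag)

    matrices: dict[str, AbundanceMatrix] = {}
    batch_offsets: dict[str, dict[str, float]] = {}
    true_cv: dict[str, float] = {}
    for tag, n_met in zip(DATASET_TAGS, config.n_metabolites_per_dataset):
        m, bo, cv = _generate_dataset(
            tag, n_met, offsets[tag], clinical, config, shifts, rng
        )
        matrices[tag] = m
        for b, d in bo.items():
            batch_offsets.setdefault(b, {}).update(d)
        true_cv.update(cv)

    truth = GroundTruth(
        effect_metabolites=effect_names,
        strong_metabolites=list(strong_names),
        true_log_shift=shifts,
        true_batch_offsets=batch_offsets,
        true_technical_cv=true_cv,
        clinical_effects={
            "family_history": {
                "control": config.clinical_params["family_history"]["control"],
                "case": config.clinical_params["family_history"]["case"],
            }
        },
    )
    return matrices, clinical, truth


# ---------------------------------------------------------------------------
# pathway database


def generate_pathway_db(
    n_pathways: int,
    universe: list[str],
    planted_pathway: list[str] | None = None,
    seed: int = 0,
    size_range: tuple[int, int] = (5, 30),
) -> pd.DataFrame:
    """KEGG-style pathway annotation table with one guaranteed-enrichable set.

    One pathway contains exactly the planted compound set; the remaining
    ``n_pathways - 1`` sample the universe uniformly at random with sizes
    drawn from ``size_range``.  Returns a DataFrame with columns
    ``pathway_id``, ``pathway_name``, ``members`` (list of compound IDs).
    """
    if not universe:
        raise ValueError("compound universe is empty")
    planted_pathway = list(planted_pathway or [])
    if not set(planted_pathway) <= set(universe):
        raise ValueError("planted pathway members must belong to the universe")
    if n_pathways < 1:
        raise ValueError("need at least one pathway")
    rng = np.random.default_rng([seed, 0x9A7])
    universe = list(universe)
    rows = []
    start = 0
    if planted_pathway:
        rows.append(("map00001", "Planted signal pathway", sorted(planted_pathway)))
        start = 1
    lo, hi = size_range
    for i in range(start, n_pathways):
        size = int(rng.integers(lo, min(hi, len(universe)) + 1))
        members = sorted(rng.choice(universe, size=max(size, 1), replace=False))
        rows.append((f"map{i + 1:05d}", f"Random pathway {i + 1}", members))
    return pd.DataFrame(rows, columns=["pathway_id", "pathway_name", "members"])


def write_pathway_db(db: pd.DataFrame, path: str | Path) -> None:
    """Persist annotations as TSV: pathway_id, name, then tab-joined members."""
    with open(path, "w") as fh:
        for _, row in db.iterrows():
            fh.write(
                "\t".join([row.pathway_id, row.pathway_name, *row.members]) + "\n"
            )
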