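"""QC filtering, imputation, transformation, batch correction and merging.

The stage order is fixed and mirrors standard untargeted LC-MS practice:

1. pooled-QC RSD filter (features with RSD > 20% are nulled),
2. missingness filter (features with > 40% missing among biological
   samples are dropped),
3. half-minimum imputation (limit-of-detection surrogate),
4. ``ln(1 + x)`` transform,
5. ComBat parametric empirical-Bayes batch correction,
6. per-feature standardization to zero mean / unit variance,
7. PCA for variance inspection and loading-based feature ranking,
8. inner-join merge of the per-mode datasets on (batch, sample) IDs.

Conventions: sample SD (``ddof=1``) throughout; filters use strict
inequalities at their thresholds (RSD exactly 20% is retained, exactly 40%
missing is imputed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .matrix import AbundanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "QCReport",
    "PCAResult",
    "compute_rsd",
    "apply_rsd_filter",
    "filter_missingness",
    "impute_half_min",
    "log1p_transform",
    "combat_correct",
    "standardize",
    "run_pca",
    "merge_datasets",
    "preprocess_dataset",
]


@dataclass
class PreprocessConfig:
    rsd_threshold: float = 20.0        # percent
    max_missing_fraction: float = 0.40
    combat_enabled: bool = True
    combat_protect_label: bool = True
    scale: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.rsd_threshold <= 100):
            raise ValueError("rsd_threshold must be in (0, 100]")
        if not (0 < self.max_missing_fraction < 1):
            raise ValueError("max_missing_fraction must be in (0, 1)")


@dataclass
class QCReport:
    """Per-metabolite QC RSDs plus the stage-by-stage retention ledger."""

    rsd: pd.Series                       # percent; +inf when the QC mean is 0
    threshold: float
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def passed(self) -> pd.Series:
        return self.rsd <= self.threshold

    def ledger_consistent(self) -> bool:
        c = self.counts
        if not {"input", "nulled_by_rsd", "dropped_by_missingness", "retained"} <= set(c):
            return False
        return c["input"] == c["nulled_by_rsd"] + c["dropped_by_missingness"] + c["retained"]


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray

    def rank_metabolites(self, component: int = 0) -> pd.Series:
        """Metabolites ordered by descending |loading| on one component."""
        load = self.loadings.iloc[:, component].abs()
        return load.sort_values(ascending=False, kind="stable")


# ---------------------------------------------------------------------------
# QC filtering


def compute_rsd(matrix: AbundanceMatrix, threshold: float = 20.0) -> QCReport:
    """Relative SD (percent) of each metabolite across pooled-QC injections.

    ``RSD_j = 100 * sd(QC_j) / mean(QC_j)`` over non-missing QC values,
    sample SD (``ddof=1``).  A zero QC mean yields ``+inf`` so the feature
    always fails the filter.
    """
    qc = matrix.qc_values()
    if qc.shape[0] < 2:
        raise ValueError("need at least 2 QC injections to compute RSDs")
    mean = qc.mean(axis=0, skipna=True)
    sd = qc.std(axis=0, ddof=1, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * sd / mean
    rsd = rsd.where(mean != 0, np.inf)
    rsd.name = "rsd_percent"
    return QCReport(rsd=rsd, threshold=threshold, counts={"input": matrix.n_metabolites})


def apply_rsd_filter(
    matrix: AbundanceMatrix, qc: QCReport, threshold: float | None = None
) -> AbundanceMatrix:
    """Null features with QC RSD above the threshold; drop QC rows.

    Features with RSD strictly greater than the threshold have every
    biological value set to missing; features at or below it pass through
    untouched.  The returned matrix contains biological samples only.
    """
    threshold = qc.threshold if threshold is None else threshold
    if not (0 < threshold <= 100):
        raise ValueError("RSD threshold must be in (0, 100]")
    if not qc.rsd.index.equals(matrix.values.columns):
        missing = matrix.values.columns.difference(qc.rsd.index)
        if len(missing):
            raise ValueError(f"QC report lacks RSDs for {len(missing)} metabolites")
    bio = matrix.biological_values().copy()
    fail = qc.rsd.loc[bio.columns] > threshold
    bio.loc[:, fail[fail].index] = np.nan
    qc.counts["nulled_by_rsd"] = int(fail.sum())
    logger.info("RSD filter: %d/%d metabolites nulled", int(fail.sum()), len(fail))
    return matrix.replace(bio)


def filter_missingness(
    matrix: AbundanceMatrix, max_missing_fraction: float = 0.40, qc: QCReport | None = None
) -> AbundanceMatrix:
    """Drop features whose missing fraction among biological samples exceeds
    the threshold (strictly greater); a feature at exactly the threshold is
    retained for imputation."""
    bio = matrix.biological_values()
    frac = bio.isna().mean(axis=0)
    keep = frac <= max_missing_fraction
    if qc is not None:
        nulled = qc.counts.get("nulled_by_rsd", 0)
        qc.counts["dropped_by_missingness"] = int((~keep).sum()) - nulled
        qc.counts["retained"] = int(keep.sum())
    logger.info(
        "missingness filter: %d dropped, %d retained", int((~keep).sum()), int(keep.sum())
    )
    return matrix.replace(bio.loc[:, keep])


# ---------------------------------------------------------------------------
# imputation / transforms


def impute_half_min(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Replace each missing cell with half the metabolite's minimum observed
    value (limit-of-detection surrogate)."""
    vals = matrix.values.copy()
    mins = vals.min(axis=0, skipna=True)
    if mins.isna().any():
        bad = list(mins.index[mins.isna()])[:5]
        raise ValueError(f"all-missing metabolites must be removed first: {bad}")
    if (mins == 0).any():
        logger.warning(
            "%d metabolites have observed minimum 0; imputing 0", int((mins == 0).sum())
        )
    filled = vals.fillna(mins / 2.0)
    return matrix.replace(filled)


def log1p_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Natural-log transform ``x -> ln(1 + x)`` to stabilize variance."""
    vals = matrix.values
    if (vals.to_numpy(dtype=float) < 0).any():
        raise ValueError("log1p requires non-negative abundances")
    return matrix.replace(np.log1p(vals))


# ---------------------------------------------------------------------------
# ComBat


def _aprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(z, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterate the empirical-Bayes posterior solutions for one batch.

    ``z`` is the (samples-in-batch x features) standardized data, ``g_hat``
    / ``d_hat`` the per-feature batch location / scale estimates, the rest
    the normal / inverse-gamma hyperparameters.
    """
    n = z.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        sum2 = ((z - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max() if np.abs(g_old).max() else 0,
            np.abs(d_new - d_old).max() / d_old.max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_correct(
    matrix: AbundanceMatrix,
    batch: pd.Series | None = None,
    protect_label: bool = True,
) -> AbundanceMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment (ComBat).

    Each feature is standardized against a model containing the batch design
    and, when ``protect_label`` is true, the case/control label as a
    protected covariate; per-batch location (gamma) and scale (delta^2)
    estimates are shrunk toward feature-ensemble priors (normal for gamma,
    inverse-gamma for delta^2) by iterating the posterior equations to
    convergence, and the adjusted values are returned on the original scale.

    With a single batch the input is returned unchanged (nothing to correct).
    """
    if batch is None:
        batch = matrix.sample_meta.loc[matrix.values.index, "batch_id"]
    batch = pd.Series(batch, index=matrix.values.index)
    if batch.isna().any():
        raise ValueError("every sample needs a batch label")
    levels = sorted(batch.unique())
    if len(levels) == 1:
        return matrix.replace(matrix.values.copy())
    counts = batch.value_counts()
    if (counts < 2).any():
        small = list(counts.index[counts < 2])
        raise ValueError(f"batches with <2 samples cannot be adjusted: {small}")

    X = matrix.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("ComBat requires complete data; impute first")
    n, p = X.shape
    onehot = np.column_stack([(batch == lv).to_numpy(float) for lv in levels])
    design = onehot
    if protect_label:
        lab = matrix.sample_meta.loc[matrix.values.index, "label"]
        if lab.notna().all() and lab.nunique() > 1:
            cand = np.column_stack([onehot, lab.to_numpy(float)])
            if np.linalg.matrix_rank(cand) < cand.shape[1]:
                # label collinear with batch: the joint fit cannot separate
                # biology from batch.  Conservative policy: attribute the
                # shared component to the protected label (estimate and
                # remove the label effect first, adjust the remainder, add
                # the label effect back).
                logger.warning(
                    "label is confounded with batch; attributing the shared "
                    "component to the protected label"
                )
                lvec = lab.to_numpy(float)
                L = np.column_stack([np.ones(n), lvec])
                coef, *_ = np.linalg.lstsq(L, X, rcond=None)
                label_part = np.outer(lvec - lvec.mean(), coef[1])
                residual = matrix.replace(
                    pd.DataFrame(
                        X - label_part,
                        index=matrix.values.index,
                        columns=matrix.values.columns,
                    )
                ).flag_transformed()
                corrected = combat_correct(residual, batch, protect_label=False)
                return matrix.replace(corrected.values + label_part)
            design = cand

    B_hat, *_ = np.linalg.lstsq(design, X, rcond=None)
    n_b = onehot.sum(axis=0)
    grand_mean = (n_b / n) @ B_hat[: len(levels)]
    var_pooled = ((X - design @ B_hat) ** 2).mean(axis=0)
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)

    stand_mean = np.tile(grand_mean, (n, 1))
    if design.shape[1] > len(levels):
        stand_mean = stand_mean + design[:, len(levels):] @ B_hat[len(levels):]
    Z = (X - stand_mean) / np.sqrt(var_pooled)[None, :]

    adjusted = Z.copy()
    for i, lv in enumerate(levels):
        sel = (batch == lv).to_numpy()
        Zb = Z[sel]
        g_hat = Zb.mean(axis=0)
        d_hat = Zb.var(axis=0, ddof=1)
        if p >= 2 and np.isfinite(g_hat).all():
            # empirical-Bayes shrinkage across the feature ensemble
            g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
            a, b = _aprior(d_hat), _bprior(d_hat)
            if t2 > 0 and np.isfinite([a, b]).all():
                g_star, d_star = _it_sol(Zb, g_hat, d_hat, g_bar, t2, a, b)
            else:
                g_star, d_star = g_hat, d_hat
        else:
            # too few features to estimate priors: unshrunk location/scale
            g_star, d_star = g_hat, d_hat
        d_star = np.where(d_star <= 0, 1.0, d_star)
        adjusted[sel] = (Zb - g_star[None, :]) / np.sqrt(d_star)[None, :]

    out = adjusted * np.sqrt(var_pooled)[None, :] + stand_mean
    return matrix.replace(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    )


# ---------------------------------------------------------------------------
# scaling / PCA / merge


def standardize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each feature to zero mean and unit sample variance (``ddof=1``);
    constant features are dropped with a warning."""
    vals = matrix.values
    if vals.isna().any().any():
        raise ValueError("standardize requires complete data; impute first")
    sd = vals.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("dropping %d constant metabolites", int(constant.sum()))
        vals = vals.loc[:, ~constant]
        sd = sd[~constant]
    z = (vals - vals.mean(axis=0)) / sd
    return matrix.replace(z).flag_transformed()


def run_pca(matrix: AbundanceMatrix, n_components: int | None = None) -> PCAResult:
    """PCA on a standardized matrix; loadings ranked by absolute value."""
    vals = matrix.values
    max_comp = min(vals.shape[0] - 1, vals.shape[1])
    if n_components is None:
        n_components = min(10, max_comp)
    if n_components > max_comp:
        raise ValueError(f"at most {max_comp} components are identifiable")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(vals.to_numpy(dtype=float))
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=vals.index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=vals.columns, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def merge_datasets(*matrices: AbundanceMatrix) -> AbundanceMatrix:
    """Inner-join the per-mode matrices on (batch_id, sample_id).

    Metabolite columns are concatenated; name collisions across datasets are
    disambiguated with a ``__<dataset>`` suffix.  Samples absent from any
    dataset (or assigned inconsistent batches) are excluded and logged.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to merge")
    keys = None
    for m in matrices:
        k = set(zip(m.values.index, m.sample_meta.loc[m.values.index, "batch_id"]))
        keys = k if keys is None else keys & k
    if not keys:
        raise ValueError("no (sample_id, batch_id) pairs shared by all datasets")
    shared = [sid for sid in matrices[0].values.index if any(sid == s for s, _ in keys)]
    dropped = set(matrices[0].values.index) - set(shared)
    if dropped:
        logger.info("merge excluded %d samples absent from some dataset", len(dropped))

    seen: dict[str, int] = {}
    frames, meta_frames = [], []
    for m in matrices:
        vals = m.values.loc[shared]
        meta = m.metabolite_meta.copy()
        rename = {}
        for c in vals.columns:
            if c in seen or any(
                c in other.values.columns for other in matrices if other is not m
            ):
                rename[c] = f"{c}__{meta.loc[c, 'dataset']}"
        if rename:
            vals = vals.rename(columns=rename)
            meta = meta.rename(index=rename)
        for c in vals.columns:
            seen[c] = 1
        frames.append(vals)
        meta_frames.append(meta)
    values = pd.concat(frames, axis=1)
    metabolite_meta = pd.concat(meta_frames, axis=0)
    sample_meta = matrices[0].sample_meta.loc[shared]
    out = AbundanceMatrix.__new__(AbundanceMatrix)
    out.values = values
    out.sample_meta = sample_meta
    out.metabolite_meta = metabolite_meta
    out.allow_negative = True
    return out


# ---------------------------------------------------------------------------
# per-dataset driver


def preprocess_dataset(
    matrix: AbundanceMatrix, config: PreprocessConfig | None = None
) -> tuple[AbundanceMatrix, QCReport]:
    """Run stages 1-6 on one acquisition mode and return the QC ledger."""
    config = config or PreprocessConfig()
    report = compute_rsd(matrix, threshold=config.rsd_threshold)
    m = apply_rsd_filter(matrix, report)
    m = filter_missingness(m, config.max_missing_fraction, qc=report)
    m = impute_half_min(m)
    m = log1p_transform(m)
    if config.combat_enabled and m.sample_meta.loc[m.values.index, "batch_id"].nunique() > 1:
        m = combat_correct(m, protect_label=config.combat_protect_label)
    if config.scale:
        m = standardize(m)
    report.counts["retained"] = m.n_metabolites
    report.counts["dropped_by_missingness"] = (
        report.counts["input"]
        - report.counts.get("nulled_by_rsd", 0)
        - report.counts["retained"]
    )
    return m, report
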