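"""Conventional-risk and integrated GDM prediction models, plus baseline-
characteristics cohort summaries.

Three nested logistic models are compared on identical complete-case
samples:

* ``1a`` — maternal age, pre-pregnancy BMI, family history of diabetes and
  venous HbA1c;
* ``1b`` — as 1a with waist-to-height ratio (WHtR) substituted for BMI;
* ``1c`` — the 1b covariates plus the selected metabolite panel
  (the integrated model).

AUCs are in-sample (apparent) with DeLong 95% CIs, matching the common
reporting style for small nested case-control cohorts; covariate lists are
configurable because published model definitions are often ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .metrics import delong_ci, threshold_metrics, youden_threshold

__all__ = [
    "ModelSpec",
    "MODEL_1A",
    "MODEL_1B",
    "RocSummary",
    "fit_risk_model",
    "compare_models",
    "summarize_tableone",
]

MODEL_1A = ("age", "bmi", "family_history", "hba1c_baseline")
MODEL_1B = ("age", "whtr", "family_history", "hba1c_baseline")


def robust_logit(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, bool]:
    """Maximum-likelihood logistic fit with a ridge fallback.

    Returns ``(params, penalized)``.  When the MLE does not exist (perfect
    separation) or the design is singular (collinear covariates), falls back
    to an L2-penalized fit so a score and ROC are still well defined.
    ``design`` must contain the intercept column first.
    """
    try:
        with np.errstate(over="ignore", divide="ignore"):
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        params = np.asarray(fit.params)
        if np.isfinite(params).all() and np.abs(params).max() <= 30:
            return params, False
    except Exception:
        pass
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(C=1.0, max_iter=1000).fit(design[:, 1:], y)
    return np.concatenate([lr.intercept_, lr.coef_[0]]), True


def _logit_scores(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    params, penalized = robust_logit(y, design)
    eta = design @ params
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35))), params, penalized


@dataclass
class ModelSpec:
    name: str
    covariates: tuple[str, ...]
    panel: tuple[str, ...] = ()

    @classmethod
    def model_1a(cls) -> "ModelSpec":
        return cls("1a", MODEL_1A)

    @classmethod
    def model_1b(cls) -> "ModelSpec":
        return cls("1b", MODEL_1B)

    @classmethod
    def model_1c(cls, panel: tuple[str, ...]) -> "ModelSpec":
        if not panel:
            raise ValueError("the integrated model 1c requires a metabolite panel")
        return cls("1c", MODEL_1B, tuple(panel))


@dataclass
class RocSummary:
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    threshold: float
    n: int
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert 0.0 <= self.auc <= 1.0
        assert self.ci_low <= self.auc <= self.ci_high


def _design(
    clinical: pd.DataFrame, spec: ModelSpec, metabolites: pd.DataFrame | None
) -> tuple[pd.DataFrame, pd.Series]:
    cols = list(spec.covariates)
    df = clinical[cols + ["gdm"]].copy()
    if spec.panel:
        if metabolites is None:
            raise ValueError("model 1c needs the metabolite matrix")
        df = df.join(metabolites[list(spec.panel)], how="inner")
    df = df.dropna()
    y = df.pop("gdm").astype(int)
    return df, y


def fit_risk_model(
    clinical: pd.DataFrame,
    spec: ModelSpec,
    metabolites: pd.DataFrame | None = None,
) -> RocSummary:
    """Logistic fit of one model spec; in-sample ROC with DeLong 95% CI.

    Rows with missing covariates are dropped (complete-case analysis);
    sensitivity/specificity are reported at the Youden-optimal threshold of
    the in-sample ROC.
    """
    X, y = _design(clinical, spec, metabolites)
    if y.nunique() < 2:
        raise ValueError("outcome has a single class after complete-case filtering")
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    scores, params, _ = _logit_scores(y.to_numpy(), design)
    auc, lo, hi = delong_ci(y.to_numpy(), scores)
    thr = youden_threshold(y.to_numpy(), scores)
    tm = threshold_metrics(y.to_numpy(), scores, thr)
    return RocSummary(
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        sensitivity=tm["sensitivity"],
        specificity=tm["specificity"],
        threshold=thr,
        n=len(y),
        coefficients=dict(zip(["intercept", *X.columns], map(float, params))),
    )


def compare_models(
    specs: list[ModelSpec],
    clinical: pd.DataFrame,
    metabolites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """AUC + CI per model, all fitted on the identical complete-case rows.

    The sample set is the intersection of complete cases across every
    spec's covariates (and panel members), so the AUCs are directly
    comparable.
    """
    all_cols: set[str] = set()
    for spec in specs:
        all_cols |= set(spec.covariates)
        all_cols |= set(spec.panel)
    frame = clinical.copy()
    if metabolites is not None:
        panel_cols = sorted(all_cols & set(metabolites.columns))
        frame = frame.join(metabolites[panel_cols], how="inner")
    use_cols = sorted(c for c in all_cols if c in frame.columns) + ["gdm"]
    complete = frame[use_cols].dropna().index
    if complete.empty:
        raise ValueError("no complete-case samples shared across models")
    rows = []
    for spec in specs:
        roc = fit_risk_model(frame.loc[complete], spec, metabolites)
        rows.append(
            {
                "model": spec.name,
                "auc": roc.auc,
                "ci_low": roc.ci_low,
                "ci_high": roc.ci_high,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "n": roc.n,
            }
        )
    return pd.DataFrame(rows).set_index("model")


# ---------------------------------------------------------------------------
# cohort description


def summarize_tableone(
    clinical: pd.DataFrame,
    group: str = "gdm",
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Baseline-characteristics table: mean +/- SD per group for continuous
    variables (two-sample t-test) and n (%) for categoricals (chi-square, or
    Fisher's exact for 2x2 tables with small expected counts)."""
    groups = clinical[group].dropna().unique()
    if len(groups) < 2:
        raise ValueError("grouping variable needs at least two levels")
    groups = sorted(groups)
    if continuous is None:
        continuous = [
            c
            for c in clinical.columns
            if c != group and pd.api.types.is_numeric_dtype(clinical[c]) and clinical[c].nunique() > 4
        ]
    if categorical is None:
        categorical = [
            c for c in clinical.columns if c != group and c not in continuous
        ]
    rows = []
    for var in continuous:
        cells, samples = {}, []
        for g in groups:
            vals = clinical.loc[clinical[group] == g, var].dropna()
            if vals.empty:
                raise ValueError(f"empty group {g!r} for variable {var!r}")
            cells[g] = f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f}"
            samples.append(vals)
        p = stats.ttest_ind(*samples[:2], equal_var=True).pvalue
        rows.append({"variable": var, **{str(g): cells[g] for g in groups}, "p_value": p})
    for var in categorical:
        tab = pd.crosstab(clinical[var], clinical[group])
        for level in tab.index:
            cells = {}
            for g in groups:
                count = int(tab.loc[level, g]) if g in tab.columns else 0
                denom = int((clinical[group] == g).sum())
                cells[str(g)] = f"{count} ({100.0 * count / denom:.1f}%)"
            rows.append({"variable": f"{var}={level}", **cells, "p_value": np.nan})
        expected = stats.contingency.expected_freq(tab.to_numpy())
        if tab.shape == (2, 2) and (expected < 5).any():
            p = stats.fisher_exact(tab.to_numpy())[1]
        else:
            p = stats.chi2_contingency(tab.to_numpy(), correction=False)[1]
        rows[-1]["p_value"] = p
    return pd.DataFrame(rows).set_index("variable")
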