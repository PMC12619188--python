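"""Random-forest biomarker panel discovery with bootstrap stability selection.

The discovery scheme mirrors a small-cohort metabolomics workflow:

1. ten stratified 70/30 train/test iterations;
2. within each training subset, random-forest hyperparameters (``mtry``,
   ``ntree``) tuned by stratified inner cross-validation on AUC;
3. features ranked by importance per iteration; the top-k ranked features
   (k = 1..10) form candidate panels, pooled across iterations with
   duplicate member sets merged;
4. every candidate panel re-validated by stratified bootstrap resampling
   (refit on each resample, metrics on the out-of-resample samples);
5. within each panel size the lowest-AUC-SD panel is flagged as the stable
   one, and among those the highest bootstrap mean AUC wins;
6. a label-permutation test quantifies how often chance alone matches the
   observed performance.

All randomness is driven by integer seeds derived from a base seed, so a
run is exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold

from .metrics import auc_score, delong_ci, threshold_metrics, youden_threshold

logger = logging.getLogger(__name__)

__all__ = [
    "SplitScheme",
    "RFGrid",
    "PanelEvaluation",
    "PermutationResult",
    "PanelDiscoveryResult",
    "stratified_split",
    "tune_random_forest",
    "rank_features",
    "enumerate_panels",
    "bootstrap_validate",
    "select_final_panel",
    "evaluate_on_test",
    "permutation_test",
    "discover_panel",
    "panel_logistic_roc",
]

_METRICS = ("auc", "sensitivity", "specificity", "accuracy", "f1")


@dataclass
class SplitScheme:
    train_fraction: float = 0.7
    n_iterations: int = 10
    inner_folds: int = 10
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.inner_folds < 2:
            raise ValueError("need at least 2 inner folds")


@dataclass
class RFGrid:
    """Candidate ``mtry`` (features per split) and ``ntree`` values."""

    mtry: tuple[int, ...] = ()
    ntree: tuple[int, ...] = (250, 500, 1000)

    @classmethod
    def default_for(cls, n_features: int, ntree: tuple[int, ...] = (250, 500, 1000)) -> "RFGrid":
        """Default mtry candidates {sqrt(p), p/3, p/2} clipped to [1, p]."""
        cands = sorted(
            {
                max(1, int(np.sqrt(n_features))),
                max(1, n_features // 3),
                max(1, n_features // 2),
            }
        )
        return cls(mtry=tuple(cands), ntree=tuple(ntree))

    def points(self) -> list[tuple[int, int]]:
        pts = [(nt, mt) for nt in self.ntree for mt in self.mtry]
        if not pts:
            raise ValueError("empty hyperparameter grid")
        if any(nt < 1 or mt < 1 for nt, mt in pts):
            raise ValueError("grid candidates must be >= 1")
        return pts


@dataclass
class PanelEvaluation:
    members: tuple[str, ...]
    test_aucs: list[float] = field(default_factory=list)
    bootstrap_mean: dict[str, float] = field(default_factory=dict)
    bootstrap_sd: dict[str, float] = field(default_factory=dict)
    stable_within_size: bool = False
    final: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class PermutationResult:
    n_permutations: int
    observed: float
    null_values: np.ndarray
    p_value: float


@dataclass
class PanelDiscoveryResult:
    evaluations: list[PanelEvaluation]
    final: PanelEvaluation
    rankings: list[pd.Series]
    splits: list[tuple[np.ndarray, np.ndarray]]
    tuned_params: list[dict]

    def table(self) -> pd.DataFrame:
        """All candidate-panel metrics, one row per panel."""
        rows = []
        for ev in self.evaluations:
            row = {
                "panel": "|".join(ev.members),
                "size": ev.size,
                "mean_test_auc": float(np.mean(ev.test_aucs)) if ev.test_aucs else np.nan,
                "stable_within_size": ev.stable_within_size,
                "final": ev.final,
            }
            for m in _METRICS:
                row[f"boot_mean_{m}"] = ev.bootstrap_mean.get(m, np.nan)
                row[f"boot_sd_{m}"] = ev.bootstrap_sd.get(m, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


def _rf(ntree: int, mtry: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=ntree, max_features=mtry, random_state=seed, n_jobs=1
    )


def _seed(base: int, *tags: int) -> int:
    """Derive a sklearn-compatible seed (< 2^31) from a base and offsets."""
    rng = np.random.default_rng([base & 0x7FFFFFFF, *tags])
    return int(rng.integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# splitting and tuning


def stratified_split(
    labels, scheme: SplitScheme, iteration: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic per-class 70/30 split for one iteration.

    Each class is shuffled with a seed derived from ``base_seed`` and the
    iteration index, and ``round(train_fraction * n_class)`` samples go to
    the training set, so a 50/50 cohort at 0.7 yields exactly 35+35 / 15+15.
    """
    y = np.asarray(labels)
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        rng = np.random.default_rng([scheme.base_seed, iteration, int(cls)])
        idx = rng.permutation(idx)
        n_train = int(round(scheme.train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.append(idx[:n_train])
        test.append(idx[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def tune_random_forest(
    X: np.ndarray,
    y: np.ndarray,
    grid: RFGrid,
    scheme: SplitScheme,
    seed: int = 0,
) -> tuple[RandomForestClassifier, dict, pd.DataFrame]:
    """Inner-CV grid search on AUC; refit the winner on the full training set.

    Run strictly on training data to avoid information leakage.  Ties on
    mean inner-CV AUC are broken toward the smaller ``ntree`` then smaller
    ``mtry`` (parsimony).  A single-point grid is selected directly.
    """
    points = grid.points()
    p = X.shape[1]
    if any(mt > p for _, mt in points):
        raise ValueError("mtry candidate exceeds the number of features")
    records = []
    if len(points) == 1:
        best = points[0]
    else:
        folds = min(scheme.inner_folds, int(np.bincount(y.astype(int)).min()))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=_seed(seed, 1))
        fold_idx = list(skf.split(X, y))
        best, best_auc = None, -np.inf
        for nt, mt in points:
            aucs = []
            for f, (tr, va) in enumerate(fold_idx):
                if len(np.unique(y[va])) < 2:
                    continue
                model = _rf(nt, mt, _seed(seed, 2, f)).fit(X[tr], y[tr])
                aucs.append(auc_score(y[va], model.predict_proba(X[va])[:, 1]))
            mean_auc = float(np.mean(aucs)) if aucs else np.nan
            records.append({"ntree": nt, "mtry": mt, "cv_auc": mean_auc})
            if mean_auc > best_auc:
                best, best_auc = (nt, mt), mean_auc
    nt, mt = best
    model = _rf(nt, mt, _seed(seed, 3)).fit(X, y)
    return model, {"ntree": nt, "mtry": mt}, pd.DataFrame(records)


def rank_features(
    model: RandomForestClassifier,
    feature_names,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
    method: str = "permutation",
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Features ordered by descending importance; ties break on name order.

    ``method='permutation'`` (mean decrease in AUC under feature shuffling,
    computed on the data supplied) is the default; ``'gini'`` uses the
    forest's impurity-based importances.
    """
    names = list(feature_names)
    if method == "permutation":
        if X is None or y is None:
            raise ValueError("permutation importance needs X and y")
        res = permutation_importance(
            model, X, y, scoring="roc_auc", n_repeats=n_repeats, random_state=_seed(seed, 4), n_jobs=1
        )
        imp = res.importances_mean
    elif method == "gini":
        imp = model.feature_importances_
    else:
        raise ValueError(f"unknown importance method {method!r}")
    s = pd.Series(imp, index=names, name="importance")
    order = sorted(range(len(names)), key=lambda j: (-s.iloc[j], names[j]))
    return s.iloc[order]


def enumerate_panels(
    rankings: list[pd.Series] | list[list[str]], max_size: int = 10
) -> list[tuple[str, ...]]:
    """Top-k candidate panels (k = 1..max_size) pooled over iterations.

    Panels with identical member sets are merged; each panel is returned as
    a name-sorted tuple, in first-seen order.
    """
    seen: dict[frozenset, tuple[str, ...]] = {}
    out: list[tuple[str, ...]] = []
    for ranking in rankings:
        names = list(ranking.index) if isinstance(ranking, pd.Series) else list(ranking)
        if max_size > len(names):
            raise ValueError("panel size exceeds the number of ranked features")
        for k in range(1, max_size + 1):
            key = frozenset(names[:k])
            if key not in seen:
                panel = tuple(sorted(names[:k]))
                seen[key] = panel
                out.append(panel)
    return out


# ---------------------------------------------------------------------------
# validation


def _roc_summary(y_true: np.ndarray, scores: np.ndarray):
    """AUC plus Youden-point threshold metrics from a single ROC pass.

    Equivalent to ``auc_score`` + ``youden_threshold`` + ``threshold_metrics``
    but computes the ROC once (hot path of the bootstrap loop).
    """
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y_true, scores)
    auc = float(np.trapezoid(tpr, fpr))
    j = int(np.argmax(tpr - fpr))
    P = int(y_true.sum())
    N = len(y_true) - P
    tp, fp = tpr[j] * P, fpr[j] * N
    tn, fn = N - fp, P - tp
    return auc, {
        "sensitivity": tpr[j],
        "specificity": 1.0 - fpr[j],
        "accuracy": (tp + tn) / len(y_true),
        "f1": 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0,
    }


def bootstrap_validate(
    X: pd.DataFrame,
    y,
    panel: tuple[str, ...],
    B: int = 1000,
    seed: int = 0,
    ntree: int = 500,
    mtry: int | None = None,
    max_redraws: int = 20,
) -> tuple[dict[str, float], dict[str, float]]:
    """Stratified bootstrap validation of one panel.

    Each of the ``B`` replicates resamples every class with replacement,
    refits the forest on the resample and evaluates AUC, sensitivity,
    specificity, accuracy and F1 on the out-of-resample samples, with the
    operating threshold at the Youden point of that replicate's ROC.
    Replicates whose out-of-resample set lacks a class are redrawn (logged).
    Returns ``(means, sds)`` per metric; the SD is 0 (with a warning) when
    ``B == 1``.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    missing = [m for m in panel if m not in X.columns]
    if missing:
        raise ValueError(f"panel members not in the data: {missing}")
    Xp = np.ascontiguousarray(X[list(panel)].to_numpy(dtype=np.float32))
    y = np.asarray(y, dtype=int)
    mtry = mtry or max(1, int(np.sqrt(len(panel))))
    cls_idx = [np.flatnonzero(y == c) for c in np.unique(y)]
    rng = np.random.default_rng([seed, 0xB001])
    vals = {m: np.empty(B) for m in _METRICS}
    n_redraws = 0
    in_oob = np.empty(len(y), dtype=bool)
    import sklearn

    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        for b in range(B):
            for _ in range(max_redraws):
                res = np.concatenate(
                    [rng.choice(idx, size=len(idx), replace=True) for idx in cls_idx]
                )
                in_oob.fill(True)
                in_oob[res] = False
                y_oob = y[in_oob]
                if y_oob.size and 0 < y_oob.sum() < y_oob.size:
                    break
                n_redraws += 1
            else:
                raise RuntimeError("could not draw a usable bootstrap replicate")
            model = _rf(ntree, mtry, int(rng.integers(0, 2**31 - 1))).fit(Xp[res], y[res])
            s = model.predict_proba(Xp[in_oob])[:, 1]
            auc, tm = _roc_summary(y_oob, s)
            vals["auc"][b] = auc
            for m in ("sensitivity", "specificity", "accuracy", "f1"):
                vals[m][b] = tm[m]
    if n_redraws:
        logger.info("bootstrap: %d replicates redrawn (degenerate OOB sets)", n_redraws)
    if B == 1:
        logger.warning("B=1: bootstrap SDs reported as 0")
    means = {m: float(v.mean()) for m, v in vals.items()}
    sds = {m: (0.0 if B == 1 else float(v.std(ddof=1))) for m, v in vals.items()}
    return means, sds


def select_final_panel(evaluations: list[PanelEvaluation]) -> PanelEvaluation:
    """Stability selection: lowest bootstrap AUC-SD within each size, then
    highest bootstrap mean AUC across sizes.

    Ties: within a size, higher mean AUC wins, then name order; across
    sizes, the smaller panel wins, then name order.  Flags are set on the
    evaluations in place.
    """
    if not evaluations:
        raise ValueError("no panel evaluations supplied")
    by_size: dict[int, list[PanelEvaluation]] = {}
    for ev in evaluations:
        ev.stable_within_size = False
        ev.final = False
        by_size.setdefault(ev.size, []).append(ev)
    stable = []
    for size, evs in by_size.items():
        best = min(
            evs,
            key=lambda e: (
                e.bootstrap_sd.get("auc", np.inf),
                -e.bootstrap_mean.get("auc", -np.inf),
                e.members,
            ),
        )
        best.stable_within_size = True
        stable.append(best)
    final = min(
        stable,
        key=lambda e: (-e.bootstrap_mean.get("auc", -np.inf), e.size, e.members),
    )
    final.final = True
    return final


def evaluate_on_test(
    X: pd.DataFrame,
    y,
    panel: tuple[str, ...],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    ntree: int = 500,
    mtry: int | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """Train-only fit; threshold metrics at the Youden point of the
    *training* ROC applied to the held-out test scores."""
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test indices overlap")
    y = np.asarray(y, dtype=int)
    if len(np.unique(y[test_idx])) < 2:
        raise ValueError("test set contains a single class")
    Xp = X[list(panel)].to_numpy(dtype=float)
    mtry = mtry or max(1, int(np.sqrt(len(panel))))
    model = _rf(ntree, mtry, _seed(seed, 5)).fit(Xp[train_idx], y[train_idx])
    thr = youden_threshold(y[train_idx], model.predict_proba(Xp[train_idx])[:, 1])
    s = model.predict_proba(Xp[test_idx])[:, 1]
    out = {"auc": auc_score(y[test_idx], s)}
    out.update(threshold_metrics(y[test_idx], s, thr))
    return out


def permutation_test(
    metric_fn,
    labels,
    P: int = 1000,
    seed: int = 0,
    observed: float | None = None,
) -> PermutationResult:
    """Label-shuffling null for any scalar performance functional.

    ``metric_fn(labels, seed)`` must rerun the full modeling procedure
    (including any tuning) and return the performance metric.  The empirical
    p-value uses the add-one convention ``(1 + #{null >= observed}) / (1 + P)``
    so it is never exactly zero.
    """
    if P < 1:
        raise ValueError("need at least one permutation")
    y = np.asarray(labels)
    if observed is None:
        observed = float(metric_fn(y, _seed(seed, 6)))
    rng = np.random.default_rng([seed, 0x9E12])
    null = np.empty(P)
    for k in range(P):
        null[k] = metric_fn(rng.permutation(y), _seed(seed, 7, k))
    p = (1.0 + float((null >= observed).sum())) / (1.0 + P)
    return PermutationResult(n_permutations=P, observed=observed, null_values=null, p_value=p)


# ---------------------------------------------------------------------------
# orchestration


def discover_panel(
    X: pd.DataFrame,
    y,
    scheme: SplitScheme | None = None,
    grid: RFGrid | None = None,
    max_panel_size: int = 10,
    B: int = 1000,
    importance: str = "permutation",
    boot_ntree: int | None = None,
    seed: int = 0,
) -> PanelDiscoveryResult:
    """End-to-end panel discovery on a (samples x features) matrix.

    Runs the split/tune/rank iterations, enumerates candidate panels,
    bootstrap-validates each, evaluates each on every iteration's held-out
    test set, and applies the lowest-SD / highest-AUC stability rule.
    ``boot_ntree`` (default: the tuned ``ntree`` of the first iteration)
    controls the forest size used inside the bootstrap loop.
    """
    scheme = scheme or SplitScheme(base_seed=seed)
    y = np.asarray(y, dtype=int)
    p = X.shape[1]
    grid = grid or RFGrid.default_for(p)
    max_panel_size = min(max_panel_size, p)

    rankings, splits, params_list = [], [], []
    for it in range(scheme.n_iterations):
        tr, te = stratified_split(y, scheme, it)
        model, params, _ = tune_random_forest(
            X.to_numpy(dtype=float)[tr], y[tr], grid, scheme, seed=_seed(seed, 10, it)
        )
        ranking = rank_features(
            model,
            X.columns,
            X.to_numpy(dtype=float)[tr],
            y[tr],
            method=importance,
            seed=_seed(seed, 11, it),
        )
        rankings.append(ranking)
        splits.append((tr, te))
        params_list.append(params)

    panels = enumerate_panels(rankings, max_panel_size)
    ntree_b = boot_ntree or params_list[0]["ntree"]
    evaluations = []
    for j, panel in enumerate(panels):
        means, sds = bootstrap_validate(
            X, y, panel, B=B, seed=_seed(seed, 12, j), ntree=ntree_b
        )
        test_aucs = [
            evaluate_on_test(X, y, panel, tr, te, ntree=ntree_b, seed=_seed(seed, 13, j, i))["auc"]
            for i, (tr, te) in enumerate(splits)
        ]
        evaluations.append(
            PanelEvaluation(
                members=panel, test_aucs=test_aucs, bootstrap_mean=means, bootstrap_sd=sds
            )
        )
    final = select_final_panel(evaluations)
    logger.info(
        "final panel (size %d): %s | boot AUC %.3f +/- %.3f",
        final.size,
        ",".join(final.members),
        final.bootstrap_mean["auc"],
        final.bootstrap_sd["auc"],
    )
    return PanelDiscoveryResult(evaluations, final, rankings, splits, params_list)


def panel_logistic_roc(X: pd.DataFrame, y, panel: tuple[str, ...]) -> dict:
    """Full-cohort logistic model on the selected panel with a DeLong CI.

    This is the headline ROC of the discovered panel: a multivariable
    logistic regression on the panel members over all samples, reported with
    the DeLong 95% CI and the Youden-point sensitivity/specificity.  When
    the panel separates the classes perfectly (small cohorts, strong
    panels), the maximum-likelihood fit does not exist and a ridge-penalized
    fit is used for the scores instead (noted in the output).
    """
    import statsmodels.api as sm

    from .clinical import _logit_scores

    y = np.asarray(y, dtype=int)
    design = sm.add_constant(X[list(panel)].to_numpy(dtype=float))
    scores, params, penalized = _logit_scores(y, design)
    auc, lo, hi = delong_ci(y, scores)
    thr = youden_threshold(y, scores)
    out = {"auc": auc, "ci_low": lo, "ci_high": hi, "threshold": thr, "penalized": penalized}
    out.update(threshold_metrics(y, scores, thr))
    out["coefficients"] = dict(zip(["intercept", *panel], map(float, params)))
    return out
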