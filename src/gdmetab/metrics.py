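"""ROC utilities: AUC, Youden operating point, threshold metrics, DeLong CI."""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "auc_score",
    "youden_threshold",
    "threshold_metrics",
    "delong_ci",
]


def auc_score(y_true, scores) -> float:
    """Area under the ROC curve (ties counted half, Mann-Whitney identity)."""
    return float(roc_auc_score(y_true, scores))


def youden_threshold(y_true, scores) -> float:
    """Score threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties in J are broken toward the higher threshold (fewer positives).
    """
    fpr, tpr, thresholds = roc_curve(y_true, scores)
    j = tpr - fpr
    return float(thresholds[int(np.argmax(j))])


def threshold_metrics(y_true, scores, threshold: float) -> dict[str, float]:
    """Sensitivity / specificity / accuracy / F1 with ``score >= threshold``
    called positive."""
    y = np.asarray(y_true, dtype=int)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    acc = (tp + tn) / len(y)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc, "f1": f1}


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_ci(y_true, scores, alpha: float = 0.95) -> tuple[float, float, float]:
    """AUC with a DeLong (1988) asymptotic confidence interval.

    Uses the structural-components formulation with midranks; returns
    ``(auc, ci_low, ci_high)`` clipped to [0, 1].
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("need both classes for a ROC curve")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n          # per-case components
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # per-control components
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = stats.norm.ppf(0.5 + alpha / 2)
    half = z * np.sqrt(var)
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))
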