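"""Evaluation suite for the quality-index regressor.

Covers regression agreement with the reference grades (RMSE, MAE, Pearson
rho), the interpretable-vs-uninterpretable screening decision (ROC, AUC,
balanced accuracy at the Youden-optimal operating point), per-feature-
subgroup ROCs, repeat-measurement threshold trade-off curves, and the
point-biserial correlation between false device rhythm decisions and
quality scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

from .features import FEATURE_NAMES, SUBGROUPS
from .model import SplitSpec, predict_aisqa, split_holdout, train

UNINTERPRETABLE_LABEL = 3
REPEAT_GRID_POINTS = 301

__all__ = [
    "EvalReport",
    "RepeatCurve",
    "DegenerateInputError",
    "regression_metrics",
    "interpretability_roc",
    "balanced_accuracy_at",
    "subgroup_roc",
    "repeat_threshold_curve",
    "false_decision_correlation",
    "evaluate_predictions",
]


class DegenerateInputError(ValueError):
    """Metric undefined on this input (constant vector or single class)."""


@dataclass
class EvalReport:
    """Regression + screening metrics of one prediction set."""

    rmse: float
    mae: float
    pearson_rho: float
    balanced_accuracy: float
    roc: dict = field(default_factory=dict)  # fpr, tpr, thresholds, auc

    def __post_init__(self) -> None:
        if self.rmse < self.mae - 1e-12:
            raise ValueError("rmse cannot be smaller than mae")


@dataclass
class RepeatCurve:
    """Repeat-measurement trade-off over the quality-score threshold."""

    thresholds: np.ndarray
    pct_repeated: np.ndarray
    pct_remaining_false: np.ndarray


def regression_metrics(y_true, y_pred) -> tuple[float, float, float]:
    """(RMSE, MAE, Pearson rho); errors on constant inputs."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    rmse = float(np.sqrt(np.mean((yt - yp) ** 2)))
    mae = float(np.mean(np.abs(yt - yp)))
    if np.std(yt) == 0 or np.std(yp) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    rho = float(stats.pearsonr(yt, yp).statistic)
    return rmse, mae, rho


def interpretability_roc(scores, labels) -> dict:
    """ROC of the binary uninterpretable decision (positive = grade 3)."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(labels) == UNINTERPRETABLE_LABEL
    if positive.all() or not positive.any():
        raise DegenerateInputError("both classes must be present")
    fpr, tpr, thr = _roc_curve(positive, scores)
    return {"fpr": fpr, "tpr": tpr, "thresholds": thr, "auc": float(_auc(fpr, tpr))}


def balanced_accuracy_at(scores, labels, threshold: float | None = None) -> float:
    """(sensitivity + specificity)/2; Youden-optimal threshold if none given."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(labels) == UNINTERPRETABLE_LABEL
    if positive.all() or not positive.any():
        raise DegenerateInputError("both classes must be present")
    if threshold is None:
        roc = interpretability_roc(scores, labels)
        youden = roc["tpr"] - roc["fpr"]
        threshold = float(roc["thresholds"][np.argmax(youden)])
    pred = scores >= threshold
    sens = float(np.mean(pred[positive]))
    spec = float(np.mean(~pred[~positive]))
    return (sens + spec) / 2.0


def subgroup_roc(
    X: np.ndarray,
    labels: np.ndarray,
    kernel: str = "exponential",
    spec: SplitSpec | None = None,
    subgroups: dict | None = None,
) -> dict[str, dict]:
    """Holdout ROC per feature subgroup plus all features, same split/seed.

    One regressor is trained per subgroup on the identical train/test split
    so the resulting AUCs are directly comparable.
    """
    spec = spec or SplitSpec()
    subgroups = subgroups or SUBGROUPS
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=float)
    idx = np.arange(len(y)).reshape(-1, 1)
    idx_tr, idx_te, y_tr, y_te = split_holdout(idx, y, spec)
    tr, te = idx_tr.ravel().astype(int), idx_te.ravel().astype(int)
    out: dict[str, dict] = {}
    groups = {**subgroups, "all": FEATURE_NAMES}
    for name, cols in groups.items():
        sel = [FEATURE_NAMES.index(c) for c in cols]
        sub = train(X[np.ix_(tr, sel)], y[tr], kernel=kernel, spec=spec)
        sub.feature_names = tuple(cols)
        preds = predict_aisqa(sub, X[np.ix_(te, sel)])
        out[name] = interpretability_roc(preds, np.round(y[te]).astype(int))
    return out


def repeat_threshold_curve(scores, false_flags, n_grid: int = REPEAT_GRID_POINTS) -> RepeatCurve:
    """Fraction repeated and fraction of surviving false decisions per threshold.

    A measurement is repeated when its quality score exceeds the threshold
    t; a false device decision survives when its recording scores <= t.
    Both fractions are relative to all recordings.
    """
    s = np.asarray(scores, dtype=float)
    flags = np.asarray(false_flags, dtype=bool)
    if s.shape != flags.shape:
        raise ValueError("scores and flags must align")
    grid = np.linspace(0.0, 3.0, n_grid)
    repeated = np.array([np.mean(s > t) for t in grid])
    remaining = np.array([np.mean(flags & (s <= t)) for t in grid])
    return RepeatCurve(thresholds=grid, pct_repeated=repeated, pct_remaining_false=remaining)


def false_decision_correlation(quality_scores, false_flags) -> tuple[float, float]:
    """Point-biserial correlation of false device decisions vs quality score."""
    s = np.asarray(quality_scores, dtype=float)
    flags = np.asarray(false_flags, dtype=float)
    if s.size < 10:
        raise ValueError("need at least 10 records")
    if np.std(flags) == 0 or np.std(s) == 0:
        raise DegenerateInputError("both flag values (and varying scores) required")
    res = stats.pearsonr(flags, s)
    return float(res.statistic), float(res.pvalue)


def evaluate_predictions(y_true, y_pred, labels=None) -> EvalReport:
    """Bundle regression metrics and, when grades are given, the screening ROC."""
    rmse, mae, rho = regression_metrics(y_true, y_pred)
    roc: dict = {}
    ba = float("nan")
    if labels is not None:
        labels = np.asarray(labels)
        if (labels == UNINTERPRETABLE_LABEL).any() and not (
            labels == UNINTERPRETABLE_LABEL
        ).all():
            roc = interpretability_roc(np.asarray(y_pred, dtype=float), labels)
            ba = balanced_accuracy_at(np.asarray(y_pred, dtype=float), labels)
    return EvalReport(rmse=rmse, mae=mae, pearson_rho=rho, balanced_accuracy=ba, roc=roc)
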