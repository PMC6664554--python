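"""Single-protein cut-off classifiers, confusion metrics, ROC curves and a
multi-marker linear combination score.

The single-marker rule mirrors the classical "high vs low at the median"
dichotomization: the cut-off is the median NPX of the pooled two-group
samples, and a sample is called positive when it lies strictly on the
positive side (values exactly at the cut-off count as "low").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .npx_core import NPXMatrix, round_half_away

__all__ = [
    "ConfusionMatrix",
    "ClassifierMetrics",
    "ROCCurve",
    "median_cutoff_classify",
    "confusion_metrics",
    "roc_curve",
    "combine_markers",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 classification counts relative to an explicit positive class."""

    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, predicted_positive, truth_positive, positive_class: str):
        pred = np.asarray(predicted_positive, dtype=bool)
        true = np.asarray(truth_positive, dtype=bool)
        if pred.shape != true.shape:
            raise ValueError("prediction/truth length mismatch")
        return cls(
            tp=int(np.sum(pred & true)),
            fp=int(np.sum(pred & ~true)),
            tn=int(np.sum(~pred & ~true)),
            fn=int(np.sum(~pred & true)),
            positive_class=positive_class,
        )


@dataclass(frozen=True)
class ClassifierMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy of a 2×2 matrix.

    A ratio with a zero denominator is reported as NaN (never as 0).
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def confusion_metrics(cm: ConfusionMatrix, round_to: int | None = None) -> ClassifierMetrics:
    """The five standard diagnostic ratios, optionally rounded (half away
    from zero) to ``round_to`` decimals as in published tables."""
    vals = {
        "sensitivity": _ratio(cm.tp, cm.tp + cm.fn, "sensitivity"),
        "specificity": _ratio(cm.tn, cm.tn + cm.fp, "specificity"),
        "ppv": _ratio(cm.tp, cm.tp + cm.fp, "PPV"),
        "npv": _ratio(cm.tn, cm.tn + cm.fn, "NPV"),
        "accuracy": _ratio(cm.tp + cm.tn, cm.total, "accuracy"),
    }
    if round_to is not None:
        vals = {k: round_half_away(v, round_to) for k, v in vals.items()}
    return ClassifierMetrics(**vals)


def median_cutoff_classify(
    values: Sequence[float],
    labels: Sequence[str],
    positive_class: str,
    direction: str | None = None,
) -> ConfusionMatrix:
    """Classify by a single protein dichotomized at the pooled median.

    The cut-off is the median over the provided (two-group) samples.
    ``direction="high"`` calls a sample positive when its value is strictly
    above the cut-off, ``"low"`` when strictly below; by default the side on
    which the positive class has the higher median is chosen.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} absent from labels")
    if classes.size < 2:
        raise ValueError("need two distinct labels")
    if np.unique(values).size == 1:
        raise ValueError("cut-off degenerate: all values identical")
    cutoff = float(np.median(values))
    truth = labels == positive_class
    if direction is None:
        direction = "high" if np.median(values[truth]) >= np.median(values[~truth]) else "low"
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")
    pred = values > cutoff if direction == "high" else values < cutoff
    return ConfusionMatrix.from_predictions(pred, truth, positive_class)


@dataclass(frozen=True)
class ROCCurve:
    """A threshold-swept ROC curve: (FPR, TPR) points from (0,0) to (1,1)
    and the trapezoid-rule area, which equals the probability a random
    positive outscores a random negative (ties half-credited)."""

    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    auc: float

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr, self.tpr))


def roc_curve(scores: Sequence[float], labels: Sequence[str], positive_class: str) -> ROCCurve:
    """ROC curve over all distinct score thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    truth = labels == positive_class
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, _ = _sk_roc_curve(truth.astype(int), scores, drop_intermediate=False)
    auc = float(roc_auc_score(truth.astype(int), scores))
    return ROCCurve(tuple(map(float, fpr)), tuple(map(float, tpr)), auc)


def combine_markers(
    matrix: NPXMatrix | np.ndarray,
    protein_ids: Sequence[str] | None,
    labels: Sequence[str],
    positive_class: str,
) -> np.ndarray:
    """Fisher linear-discriminant score combining several proteins.

    Fits ``w ∝ S_w⁻¹ (μ_pos − μ_neg)`` on the provided samples (pooled
    within-class covariance) and returns one scalar score per sample,
    oriented so higher scores are more positive-class-like. A singular pooled
    covariance falls back to its diagonal with a warning.
    """
    if isinstance(matrix, NPXMatrix):
        if protein_ids is None:
            raise ValueError("protein_ids required with an NPXMatrix input")
        X = np.column_stack([matrix.column(p) for p in protein_ids])
    else:
        X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("combine_markers needs at least two proteins")
    labels = np.asarray(labels)
    truth = labels == positive_class
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present")
    mu_pos = X[truth].mean(axis=0)
    mu_neg = X[~truth].mean(axis=0)
    centered = np.vstack([X[truth] - mu_pos, X[~truth] - mu_neg])
    sw = centered.T @ centered / max(len(X) - 2, 1)
    try:
        w = linalg.solve(sw, mu_pos - mu_neg, assume_a="pos")
    except linalg.LinAlgError:
        warnings.warn("singular pooled covariance; falling back to diagonal", stacklevel=2)
        diag = np.diag(sw).copy()
        diag[diag == 0] = 1.0
        w = (mu_pos - mu_neg) / diag
    scores = X @ w
    # orient: positive class should score higher
    if np.mean(scores[truth]) < np.mean(scores[~truth]):
        scores = -scores
    return scores
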