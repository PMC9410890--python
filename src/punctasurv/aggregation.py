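"""CV-based aggregate classification: ROC calibration and per-ROI/neuron calls.

The aggregate score is the coefficient of variation (CV) of reporter
intensity within an ROI. The classification rule is ``CV >= threshold =>
aggregated``; a CV exactly at the threshold counts as aggregated (a fixed
boundary convention is required for bit-reproducible calls). The operating
threshold used throughout the assay is 1.0; the ROC machinery here exists to
validate that choice on a labeled ROI set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import NoUsableROIError, UndefinedCVError

__all__ = [
    "ROCCurve",
    "roc_curve",
    "youden_threshold",
    "classify_roi",
    "classify_neuron",
    "confusion_metrics",
    "CVThresholdClassifier",
]

AGGREGATED, DIFFUSE = "aggregated", "diffuse"


@dataclass(frozen=True)
class ROCCurve:
    """ROC over candidate CV thresholds with the rule score >= t => positive.

    ``thresholds`` are in ascending order: the distinct observed scores plus
    a +inf sentinel, so the curve runs from (FPR, TPR) = (1, 1) at the lowest
    score down to (0, 0) at the sentinel. Tied scores collapse into a single
    threshold step. ``auc`` is the trapezoid-rule area, which equals the
    Mann-Whitney U statistic divided by n_pos * n_neg.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _as_label_array(labels: Sequence) -> np.ndarray:
    """Coerce labels to a boolean array (True = aggregated)."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "bi":
        return arr.astype(bool)
    if arr.dtype.kind in "UO":
        valid = {AGGREGATED, DIFFUSE}
        bad = set(arr.tolist()) - valid
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}; expected {valid}")
        return arr == AGGREGATED
    raise ValueError(f"cannot interpret labels of dtype {arr.dtype}")


def roc_curve(scores: Sequence[float], labels: Sequence) -> ROCCurve:
    """Build the ROC curve of the CV score on a labeled ROI set.

    Parameters
    ----------
    scores
        Per-ROI CV values (finite, >= 0).
    labels
        True phenotypes: booleans (True = aggregated) or the strings
        'aggregated' / 'diffuse'. Both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_label_array(labels)
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-d sequences")
    if not np.all(np.isfinite(scores)):
        raise ValueError("all scores must be finite")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    thresholds = np.concatenate([np.unique(scores), [np.inf]])
    pos_sorted = np.sort(scores[y])
    neg_sorted = np.sort(scores[~y])
    # count of class scores >= t via binary search on the sorted class arrays
    tpr = (n_pos - np.searchsorted(pos_sorted, thresholds, side="left")) / n_pos
    fpr = (n_neg - np.searchsorted(neg_sorted, thresholds, side="left")) / n_neg
    # fpr is non-increasing in threshold; integrate in ascending-fpr order
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def youden_threshold(roc: ROCCurve) -> float:
    """Threshold maximizing Youden's J = TPR - FPR over observed scores.

    Ties are broken toward the larger (more specific) threshold. The +inf
    sentinel is not a candidate; a degenerate single-score ROC returns that
    score.
    """
    finite = np.isfinite(roc.thresholds)
    j = roc.tpr[finite] - roc.fpr[finite]
    thresholds = roc.thresholds[finite]
    best = j.max()
    return float(thresholds[np.isclose(j, best)].max())


def classify_roi(cv: float, threshold: float = 1.0) -> bool:
    """Call one ROI: True (aggregated) iff CV >= threshold.

    Raises :class:`UndefinedCVError` for NaN CVs (undefined-CV ROIs must be
    excluded upstream, not silently called diffuse).
    """
    if math.isnan(cv):
        raise UndefinedCVError("cannot classify an ROI with undefined CV")
    return bool(cv >= threshold)


def classify_neuron(cvs: Iterable[float], threshold: float = 1.0) -> bool:
    """Neuron-level call: aggregate-bearing iff ANY live-timepoint ROI has
    CV >= threshold.

    NaN CVs (undefined, e.g. non-positive mean) are ignored; if no usable CV
    remains the neuron cannot be classified and :class:`NoUsableROIError` is
    raised so callers can exclude and log it.
    """
    arr = np.asarray(list(cvs), dtype=float)
    usable = arr[~np.isnan(arr)]
    if usable.size == 0:
        raise NoUsableROIError("neuron has no live ROI with a defined CV")
    return bool(np.any(usable >= threshold))


def confusion_metrics(calls: Sequence, labels: Sequence) -> tuple[float, float]:
    """(sensitivity, specificity) of aggregate calls against true labels.

    Sensitivity = TP / (TP + FN) over truly aggregated ROIs; specificity =
    TN / (TN + FP) over truly diffuse ROIs. Raises if either class is empty.
    """
    calls_b = _as_label_array(calls)
    labels_b = _as_label_array(labels)
    if calls_b.shape != labels_b.shape:
        raise ValueError("calls and labels must be aligned")
    n_pos = int(labels_b.sum())
    n_neg = int((~labels_b).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("confusion metrics require both classes present")
    sensitivity = float((calls_b & labels_b).sum() / n_pos)
    specificity = float((~calls_b & ~labels_b).sum() / n_neg)
    return sensitivity, specificity


class CVThresholdClassifier:
    """Scikit-learn-style wrapper around the CV threshold rule.

    With ``threshold=None`` (default), :meth:`fit` selects the Youden-optimal
    threshold from the ROC on the training scores; with a numeric
    ``threshold`` the classifier is fixed (e.g. the assay's operating point
    of 1.0) and fit only computes validation metrics.

    Fitted attributes: ``threshold_``, ``roc_``, ``auc_``, ``sensitivity_``,
    ``specificity_``.
    """

    def __init__(self, threshold: float | None = None):
        self.threshold = threshold

    # minimal get/set_params so sklearn.clone and pipelines work without the
    # package depending on sklearn itself
    def get_params(self, deep: bool = True) -> dict:
        return {"threshold": self.threshold}

    def set_params(self, **params) -> "CVThresholdClassifier":
        for k, v in params.items():
            if k not in {"threshold"}:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _scores(X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 1:
            arr = arr[:, 0]
        if arr.ndim != 1:
            raise ValueError("X must be a 1-d CV array or an (n, 1) column")
        return arr

    def fit(self, X, y) -> "CVThresholdClassifier":
        scores = self._scores(X)
        self.roc_ = roc_curve(scores, y)
        self.auc_ = self.roc_.auc
        self.threshold_ = (
            youden_threshold(self.roc_) if self.threshold is None else float(self.threshold)
        )
        calls = scores >= self.threshold_
        self.sensitivity_, self.specificity_ = confusion_metrics(
            calls, _as_label_array(y)
        )
        self.classes_ = np.array([DIFFUSE, AGGREGATED])
        return self

    def decision_function(self, X) -> np.ndarray:
        return self._scores(X)

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "threshold_"):
            raise RuntimeError("classifier is not fitted")
        scores = self._scores(X)
        if np.any(np.isnan(scores)):
            raise UndefinedCVError("cannot classify ROIs with undefined CV")
        return np.where(scores >= self.threshold_, AGGREGATED, DIFFUSE)
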