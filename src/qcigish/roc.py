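"""ROC curves and optimal-threshold selection for diagnostic scores.

Curves are built over the candidate cutoffs a continuous score actually
admits: the midpoints between consecutive distinct observed values, plus
sentinels below and above everything.  A sample is called positive when
its score is at or above the cutoff (higher score = more malignant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

POSITIVE_LABEL = "malignant"


@dataclass(frozen=True)
class RocCurve:
    """Operating points of a score against a binary truth.

    ``thresholds`` ascend; ``sensitivity`` is non-increasing and
    ``specificity`` non-decreasing along them.  ``auc`` is the area under
    the (1-specificity, sensitivity) polyline, which for this threshold
    set equals the Mann-Whitney probability that a random positive scores
    above a random negative (ties counted half).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def __len__(self) -> int:
        return len(self.thresholds)


def _as_bool_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    return arr == POSITIVE_LABEL


def roc_curve(scores, labels) -> RocCurve:
    """Build a ROC curve from per-sample scores and benign/malignant labels.

    ``labels`` may be booleans (True = positive class) or the strings
    ``"benign"``/``"malignant"``.  Both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    pos_mask = _as_bool_labels(labels)
    if scores.shape != pos_mask.shape:
        raise ValueError("scores and labels differ in length")
    if scores.size < 2:
        raise ValueError("ROC requires at least two samples")
    pos = np.sort(scores[pos_mask])
    neg = np.sort(scores[~pos_mask])
    if pos.size == 0 or neg.size == 0:
        raise ValueError("ROC requires both classes present")

    uniq = np.unique(scores)
    thresholds = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    # positive call: score >= threshold (thresholds never equal data values
    # except the +/-inf sentinels, so >= and > coincide)
    sensitivity = 1.0 - np.searchsorted(pos, thresholds, side="left") / pos.size
    specificity = np.searchsorted(neg, thresholds, side="left") / neg.size

    fpr = 1.0 - specificity
    # thresholds ascend => fpr descends; integrate in ascending-fpr order
    auc = float(np.trapezoid(sensitivity[::-1], fpr[::-1]))
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sensitivity,
        specificity=specificity,
        auc=auc,
    )


def optimal_threshold(curve: RocCurve) -> float:
    """Cutoff maximising Youden's J = sensitivity + specificity - 1.

    Ties are broken toward higher specificity, then toward the lower
    threshold, so the result is deterministic.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    # lexsort: last key is primary
    order = np.lexsort((curve.thresholds, -curve.specificity, -j))
    return float(curve.thresholds[order[0]])
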