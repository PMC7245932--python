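"""Confusion-matrix evaluation of benign/malignant predictions.

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP) and accuracy =
(TP+TN)/total, all as percentages.  Exact values are carried as floats;
reports round to the nearest integer percent, half away from zero.  A
rate whose class is empty is undefined (``None``), never silently zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

POSITIVE = "malignant"
NEGATIVE = "benign"


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ConfusionSummary:
    """TN/FP/FN/TP with derived operating characteristics."""

    tn: int
    fp: int
    fn: int
    tp: int

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else None

    @property
    def accuracy(self) -> float | None:
        return 100.0 * (self.tp + self.tn) / self.total if self.total else None

    def rounded(self) -> dict[str, int | None]:
        """Integer-percent report (sensitivity, specificity, accuracy)."""
        return {
            name: None if value is None else round_half_up(value)
            for name, value in (
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("accuracy", self.accuracy),
            )
        }

    def __add__(self, other: "ConfusionSummary") -> "ConfusionSummary":
        return ConfusionSummary(
            self.tn + other.tn, self.fp + other.fp, self.fn + other.fn, self.tp + other.tp
        )


def evaluate(predictions: Sequence[str], truth: Sequence[str]) -> ConfusionSummary:
    """Tally a confusion matrix from aligned prediction/truth labels."""
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth differ in length")
    tn = fp = fn = tp = 0
    for pred, actual in zip(predictions, truth):
        if actual not in (POSITIVE, NEGATIVE) or pred not in (POSITIVE, NEGATIVE):
            raise ValueError(f"labels must be {NEGATIVE!r}/{POSITIVE!r}: {pred!r}/{actual!r}")
        if actual == POSITIVE:
            tp += pred == POSITIVE
            fn += pred == NEGATIVE
        else:
            tn += pred == NEGATIVE
            fp += pred == POSITIVE
    if tp + fn == 0:
        warnings.warn("no malignant samples: sensitivity undefined", stacklevel=2)
    if tn + fp == 0:
        warnings.warn("no benign samples: specificity undefined", stacklevel=2)
    return ConfusionSummary(tn=tn, fp=fp, fn=fn, tp=tp)


def evaluation_report(
    per_cancer: Mapping[str, ConfusionSummary], *, overall_label: str = "total"
) -> pd.DataFrame:
    """Per-cancer-type performance table with a pooled overall row."""
    rows = []
    overall = ConfusionSummary(0, 0, 0, 0)
    for cancer_type in sorted(per_cancer):
        s = per_cancer[cancer_type]
        overall = overall + s
        rows.append({"cancer_type": cancer_type, **_row(s)})
    rows.append({"cancer_type": overall_label, **_row(overall)})
    return pd.DataFrame(rows)


def _row(s: ConfusionSummary) -> dict:
    r = s.rounded()
    return {
        "sensitivity": r["sensitivity"],
        "specificity": r["specificity"],
        "tn": s.tn,
        "fp": s.fp,
        "fn": s.fn,
        "tp": s.tp,
    }


#: Confusion counts of the cancer-specific diagnostic models as published
#: for the ten-cancer clinical study this pipeline's design follows
#: (benign column split into imprinting-negative/positive = TN/FP, malignant
#: into FN/TP).  They serve as a cross-check that the evaluation arithmetic
#: reproduces the reported operating characteristics; the underlying raw
#: counts per nucleus were never deposited.
CLINICAL_STUDY_CONFUSION: Mapping[str, ConfusionSummary] = {
    "bladder": ConfusionSummary(tn=27, fp=1, fn=1, tp=59),
    "breast": ConfusionSummary(tn=25, fp=1, fn=1, tp=60),
    "colorectal": ConfusionSummary(tn=15, fp=1, fn=1, tp=41),
    "esophagus": ConfusionSummary(tn=16, fp=2, fn=2, tp=39),
    "gastric": ConfusionSummary(tn=17, fp=1, fn=3, tp=39),
    "lung": ConfusionSummary(tn=23, fp=3, fn=13, tp=141),
    "pancreatic": ConfusionSummary(tn=19, fp=2, fn=3, tp=41),
    "prostate": ConfusionSummary(tn=15, fp=2, fn=3, tp=42),
    "skin": ConfusionSummary(tn=12, fp=1, fn=1, tp=37),
    "thyroid": ConfusionSummary(tn=18, fp=3, fn=12, tp=115),
}

#: Published integer-percent (sensitivity, specificity) per cancer type,
#: plus the pooled row; the pooled accuracy was reported as 93%.
CLINICAL_STUDY_REPORTED: Mapping[str, tuple[int, int]] = {
    "bladder": (98, 96),
    "breast": (98, 96),
    "colorectal": (98, 94),
    "esophagus": (95, 89),
    "gastric": (93, 94),
    "lung": (92, 88),
    "pancreatic": (93, 90),
    "prostate": (93, 88),
    "skin": (97, 92),
    "thyroid": (91, 86),
    "total": (94, 92),
}
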