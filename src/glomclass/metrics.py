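"""Confusion matrix and evaluation metrics.

Positive class = sclerotic.  Accuracy, precision, recall and the Matthews
correlation coefficient (MCC) are computed from the TP/FP/FN/TN counts:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    MCC       = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC is the correlation between predicted and true binary labels (1 perfect,
0 random, -1 inverted) and is the model-selection criterion of choice under
the heavy class imbalance of this problem.  Any metric whose denominator is
zero is defined as 0 and flagged, matching the random-predictor semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive = sclerotic."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion_matrix(true_labels, predicted_labels, pos_label=1) -> ConfusionMatrix:
    """Count TP/FP/FN/TN over paired binary label sequences."""
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    tp = fp = fn = tn = 0
    for ti, pi in zip(t, p):
        if pi == pos_label:
            if ti == pos_label:
                tp += 1
            else:
                fp += 1
        else:
            if ti == pos_label:
                fn += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, fp, fn, tn)


def mcc_score(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 (flag-free) if a marginal is empty."""
    tp, fp, fn, tn = cm.TP, cm.FP, cm.FN, cm.TN
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def classification_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, precision, recall and MCC with zero-denominator flags.

    Returns a dict with the four metric values plus ``flags``: the names of
    metrics whose denominator was zero (reported as 0).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = cm.TP, cm.FP, cm.FN, cm.TN
    flags: list[str] = []

    accuracy = (tp + tn) / cm.total
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, flags = 0.0, flags + ["precision"]
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, flags = 0.0, flags + ["recall"]
    if (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn) == 0:
        mcc = 0.0
        flags = flags + ["mcc"]
    else:
        mcc = mcc_score(cm)
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "mcc": mcc,
        "flags": flags,
    }


def round4(value: float) -> float:
    """Report rounding used in result tables: 4 decimals, round-half-even."""
    return float(f"{value:.4f}")
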