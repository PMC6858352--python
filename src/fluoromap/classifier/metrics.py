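"""Patch-level evaluation: accuracy, confusion counts, ROC and AUC."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from ..patches import NEGATIVE, POSITIVE, PatchRecord
from .base import PatchClassifier

__all__ = ["PatchMetrics", "evaluate_patches"]


@dataclass(frozen=True)
class PatchMetrics:
    """Evaluation summary over a labeled patch set.

    ``auc`` and ``roc_points`` are None when the set is single-class (AUC is
    undefined there; it is reported as absent, never as 0).
    """

    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None
    roc_points: tuple[np.ndarray, np.ndarray] | None  # (fpr, tpr)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def evaluate_patches(classifier: PatchClassifier,
                     test: Sequence[PatchRecord]) -> PatchMetrics:
    """Score a classifier on labeled patches.

    Probabilities are binarized at 0.5 with ties going to positive
    (p >= 0.5 is a positive call).  The ROC curve is a threshold sweep over
    the emitted probabilities.
    """
    if not test:
        raise ValueError("test set must be non-empty")
    y_true = []
    for rec in test:
        if rec.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"cannot evaluate patch labeled {rec.label!r}")
        y_true.append(1 if rec.label == POSITIVE else 0)
    y_true = np.asarray(y_true)
    probs = np.asarray(classifier.predict_proba_batch(
        [rec.pixels for rec in test]))
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("classifier emitted probabilities outside [0, 1]")

    y_pred = (probs >= 0.5).astype(int)
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    tn = int(((y_pred == 0) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    accuracy = (tp + tn) / len(y_true)

    if len(np.unique(y_true)) < 2:
        auc, roc_points = None, None
    else:
        auc = float(roc_auc_score(y_true, probs))
        fpr, tpr, _ = roc_curve(y_true, probs)
        roc_points = (fpr, tpr)
    return PatchMetrics(accuracy=accuracy, tp=tp, fp=fp, tn=tn, fn=fn,
                        auc=auc, roc_points=roc_points)
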