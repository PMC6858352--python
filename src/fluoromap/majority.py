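"""Majority-decision voting on prediction maps and per-image diagnosis.

A square vote window slides over the binary map one map pixel at a time
(valid positions only, no padding); an output pixel is 1 iff the fraction of
positive pixels inside the window *strictly exceeds* the threshold.  The
output therefore shrinks by ``vote_window - 1`` pixels per axis — at step 10
this crops half the 278 px analysis window from each side of the mapped
frame, removing the mirrored border.  An image is called positive iff the
filtered map contains at least one positive pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._integral import box_sums
from .mapper import PredictionMap
from .synthetic import Status

__all__ = [
    "VOTE_WINDOWS",
    "vote_window_for_step",
    "MajorityConfig",
    "DecisionResult",
    "EvaluationTable",
    "majority_vote",
    "decide_image",
    "threshold_sweep",
    "PAPER_THRESHOLDS",
]

# Vote-window sizes per mapping step, a verbatim lookup: 278/step rounds
# inconsistently across the three steps (27.8 -> 27, 7.94 -> 8, 3.97 -> 4),
# so the table takes precedence over the generic fallback.
VOTE_WINDOWS = {10: 27, 35: 8, 70: 4}

PAPER_THRESHOLDS = (0.40, 0.50, 0.60, 0.70, 0.80, 0.90)


def vote_window_for_step(step: int, patch_size: int = 278) -> int:
    """Vote-window size for a mapping step (table first, rounding fallback)."""
    if step in VOTE_WINDOWS and patch_size == 278:
        return VOTE_WINDOWS[step]
    return max(1, round(patch_size / step))


@dataclass(frozen=True)
class MajorityConfig:
    """Vote-window size and strict positive-fraction threshold."""

    vote_window: int = 27
    threshold: float = 0.7

    def __post_init__(self) -> None:
        if self.vote_window < 1:
            raise ValueError("vote_window must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")

    @classmethod
    def for_step(cls, step: int, threshold: float = 0.7,
                 patch_size: int = 278) -> "MajorityConfig":
        return cls(vote_window=vote_window_for_step(step, patch_size),
                   threshold=threshold)


@dataclass(frozen=True)
class DecisionResult:
    """Final per-image call: positive iff any filtered pixel is positive."""

    filtered_map: np.ndarray
    image_call: Status
    positive_pixel_count: int


def majority_vote(prediction: PredictionMap | np.ndarray,
                  config: MajorityConfig) -> np.ndarray:
    """Windowed majority vote over a binary map.

    Output pixel (i, j) corresponds to the vote window whose top-left input
    pixel is (i, j); it is 1 iff ``count / vote_window**2 > threshold``
    (strict).  Output dims are ``(n_rows - k + 1, n_cols - k + 1)``.
    """
    grid = prediction.grid if isinstance(prediction, PredictionMap) \
        else np.asarray(prediction)
    if not np.isin(grid, (0, 1)).all():
        raise ValueError("map entries must be 0/1")
    k = config.vote_window
    n_rows, n_cols = grid.shape
    if n_rows < k or n_cols < k:
        raise ValueError(
            f"map {n_rows}x{n_cols} smaller than vote window {k}"
        )
    rows = np.arange(n_rows - k + 1)
    cols = np.arange(n_cols - k + 1)
    counts = box_sums(grid.astype(np.uint8), k, rows, cols)
    out = counts > config.threshold * (k * k)
    return out.astype(np.uint8)


def decide_image(filtered: np.ndarray) -> DecisionResult:
    """Per-image call: positive iff at least one pixel is set."""
    filtered = np.asarray(filtered)
    count = int(filtered.sum())
    call = Status.POSITIVE if count >= 1 else Status.NEGATIVE
    return DecisionResult(filtered_map=filtered, image_call=call,
                          positive_pixel_count=count)


@dataclass
class EvaluationTable:
    """Per-threshold true-prediction rates over a set of images.

    One row per threshold plus a leading no-filter row; columns carry the
    fraction (and counts) of positive images called positive and negative
    images called negative.
    """

    rows: list[dict] = field(default_factory=list)

    def add_row(self, label: str, pos_correct: int, n_pos: int,
                neg_correct: int, n_neg: int) -> None:
        self.rows.append({
            "threshold": label,
            "positive_true_rate": pos_correct / n_pos if n_pos else float("nan"),
            "negative_true_rate": neg_correct / n_neg if n_neg else float("nan"),
            "positive_correct": pos_correct,
            "n_positive": n_pos,
            "negative_correct": neg_correct,
            "n_negative": n_neg,
        })

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def rate(self, threshold_label: str, cls: str) -> float:
        for row in self.rows:
            if row["threshold"] == threshold_label:
                return row[f"{cls}_true_rate"]
        raise KeyError(threshold_label)


def threshold_sweep(maps: Sequence[tuple[PredictionMap, Status]],
                    thresholds: Iterable[float] = PAPER_THRESHOLDS,
                    vote_window: int | None = None) -> EvaluationTable:
    """Evaluate per-image calls with and without majority filtering.

    ``maps`` pairs each prediction map with the image's true status.  The
    first row ("none") decides on the raw map; one row per threshold decides
    on the majority-filtered map.  The vote window defaults to the per-step
    lookup of each map's step.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no maps supplied")
    statuses = {status for _, status in maps}
    if statuses != {Status.POSITIVE, Status.NEGATIVE}:
        raise ValueError("need at least one map per class")

    table = EvaluationTable()
    n_pos = sum(1 for _, s in maps if s is Status.POSITIVE)
    n_neg = len(maps) - n_pos

    def tally(call_fn) -> tuple[int, int]:
        pos_ok = neg_ok = 0
        for pmap, status in maps:
            call = call_fn(pmap)
            if status is Status.POSITIVE and call is Status.POSITIVE:
                pos_ok += 1
            elif status is Status.NEGATIVE and call is Status.NEGATIVE:
                neg_ok += 1
        return pos_ok, neg_ok

    pos_ok, neg_ok = tally(lambda pm: decide_image(pm.grid).image_call)
    table.add_row("none", pos_ok, n_pos, neg_ok, n_neg)

    for thr in thresholds:
        def call(pm: PredictionMap, thr: float = thr) -> Status:
            k = vote_window if vote_window is not None \
                else vote_window_for_step(pm.step, pm.patch_size)
            cfg = MajorityConfig(vote_window=k, threshold=thr)
            return decide_image(majority_vote(pm, cfg)).image_call

        pos_ok, neg_ok = tally(call)
        table.add_row(f"{thr:.2f}", pos_ok, n_pos, neg_ok, n_neg)
    return table
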