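"""Patch extraction, normalization, labeling and leakage-free splits.

Frames are tiled into non-overlapping 278 x 278 patches from the top-left
origin (0-based, row-major; residual right/bottom margins are discarded).
Each patch is normalized by the single scalar maximum over all pixels and
channels.  Labeling follows the asymmetric policy: patches from positive
nodes are positive only when they contain tumor, otherwise *excluded*;
patches from negative nodes are always negative.  Splits are grouped by
node id so no node contributes to more than one of train/validation/test.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .synthetic import LabeledImage, Status

logger = logging.getLogger(__name__)

__all__ = [
    "PATCH_SIZE",
    "PatchRecord",
    "DatasetSplit",
    "PatchAccounting",
    "divide_into_patches",
    "normalize_patch",
    "label_patch",
    "label_patches",
    "extract_labeled_patches",
    "split_by_node",
]

PATCH_SIZE = 278

POSITIVE = "positive"
NEGATIVE = "negative"
EXCLUDED = "excluded"


@dataclass
class PatchRecord:
    """One normalized patch with grid position, label and provenance."""

    pixels: np.ndarray          # (patch, patch, 3) float in [0, 1]
    grid_row: int
    grid_col: int
    source_image: str           # node_id of the originating frame
    label: str = EXCLUDED
    tumor_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.label == POSITIVE and self.tumor_fraction <= 0:
            raise ValueError("positive label requires tumor_fraction > 0")


@dataclass
class DatasetSplit:
    """Node-grouped train/validation/test partition of patch records."""

    train: list[PatchRecord] = field(default_factory=list)
    validation: list[PatchRecord] = field(default_factory=list)
    test: list[PatchRecord] = field(default_factory=list)
    group_map: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class PatchAccounting:
    """Per-label patch counts for a dataset (manifest-level bookkeeping)."""

    n_positive: int
    n_negative: int
    n_excluded: int = 0

    @classmethod
    def from_records(cls, records: "list[PatchRecord]") -> "PatchAccounting":
        counts = Counter(rec.label for rec in records)
        return cls(n_positive=counts.get(POSITIVE, 0),
                   n_negative=counts.get(NEGATIVE, 0),
                   n_excluded=counts.get(EXCLUDED, 0))

    @property
    def total_used(self) -> int:
        """Positive + negative patches actually used for model development."""
        return self.n_positive + self.n_negative

    @property
    def total(self) -> int:
        return self.n_positive + self.n_negative + self.n_excluded


def normalize_patch(raw: np.ndarray) -> np.ndarray:
    """Divide all channels by the single scalar max over pixels and channels.

    Output lies in [0, 1] with max exactly 1.0; the relative channel ratios
    are preserved.  An all-zero patch is returned unchanged (degenerate case,
    logged as a warning).
    """
    raw = np.asarray(raw)
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) patch")
    out = raw.astype(np.float64)
    peak = out.max()
    if peak == 0:
        logger.warning("normalize_patch: all-zero patch left unchanged")
        return out
    return out / peak


def divide_into_patches(image: LabeledImage,
                        patch_size: int = PATCH_SIZE) -> list[PatchRecord]:
    """Tile a frame into non-overlapping normalized patches.

    Returns floor(H/patch) x floor(W/patch) records in row-major order with
    0-based grid indices; right/bottom residuals are discarded.  Labels are
    left as ``excluded`` — apply :func:`label_patches` to assign them.
    """
    h, w = image.shape
    if h < patch_size or w < patch_size:
        raise ValueError(
            f"image {h}x{w} smaller than patch size {patch_size}"
        )
    n_rows, n_cols = h // patch_size, w // patch_size
    records = []
    denom = float(patch_size * patch_size)
    for r in range(n_rows):
        for c in range(n_cols):
            ys = slice(r * patch_size, (r + 1) * patch_size)
            xs = slice(c * patch_size, (c + 1) * patch_size)
            records.append(PatchRecord(
                pixels=normalize_patch(image.rgb[ys, xs]),
                grid_row=r,
                grid_col=c,
                source_image=image.node_id,
                tumor_fraction=float(image.mask[ys, xs].sum()) / denom,
            ))
    return records


def is_tumor_positive(tumor_fraction: float,
                      min_tumor_fraction: float = 0.0) -> bool:
    """Tumor-presence rule shared by patch labeling and window ground truth.

    Default ``min_tumor_fraction=0.0`` means *any* positive pixel counts.
    """
    return tumor_fraction > 0 and tumor_fraction >= min_tumor_fraction


def label_patch(tumor_fraction: float, node_status: Status,
                min_tumor_fraction: float = 0.0) -> str:
    """Assign a label under the asymmetric positive/negative-node policy.

    Patches from negative nodes are always ``negative``.  Patches from
    positive nodes are ``positive`` when tumor is present at or above
    ``min_tumor_fraction``, otherwise ``excluded`` — never negative.
    """
    if node_status is Status.NEGATIVE:
        return NEGATIVE
    if is_tumor_positive(tumor_fraction, min_tumor_fraction):
        return POSITIVE
    return EXCLUDED


def label_patches(records: list[PatchRecord], image: LabeledImage,
                  min_tumor_fraction: float = 0.0) -> list[PatchRecord]:
    """Label records in place from their image's status; returns the list."""
    for rec in records:
        rec.label = label_patch(rec.tumor_fraction, image.status,
                                min_tumor_fraction)
    return records


def extract_labeled_patches(image: LabeledImage,
                            patch_size: int = PATCH_SIZE,
                            min_tumor_fraction: float = 0.0) -> list[PatchRecord]:
    """Tile, normalize and label one frame in a single call."""
    return label_patches(divide_into_patches(image, patch_size), image,
                         min_tumor_fraction)


def _allocate(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Largest-remainder allocation of n items over three fractions."""
    raw = [n * f for f in fractions]
    counts = [int(x) for x in raw]
    # every requested (fraction > 0) split gets at least one item
    for i, f in enumerate(fractions):
        if f > 0 and counts[i] == 0:
            counts[i] = 1
    while sum(counts) > n:
        i = max(range(3), key=lambda k: counts[k] - raw[k])
        counts[i] -= 1
    while sum(counts) < n:
        i = max(range(3), key=lambda k: raw[k] - counts[k])
        counts[i] += 1
    return counts


def split_by_node(patches: list[PatchRecord],
                  fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                  seed: int = 0) -> DatasetSplit:
    """Partition patches into train/validation/test grouped by node id.

    Node ids are shuffled and allocated per class (the class of a node is
    positive if any of its patches is positive), so each split receives
    whole nodes only and, when feasible, both classes.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    by_node: dict[str, list[PatchRecord]] = defaultdict(list)
    for rec in patches:
        by_node[rec.source_image].append(rec)

    node_class = {
        node: POSITIVE if any(r.label == POSITIVE for r in recs) else NEGATIVE
        for node, recs in by_node.items()
    }
    n_requested = sum(1 for f in fractions if f > 0)
    rng = np.random.default_rng(seed)
    split = DatasetSplit()
    names = ("train", "validation", "test")
    for cls in (POSITIVE, NEGATIVE):
        nodes = sorted(n for n, c in node_class.items() if c == cls)
        if not nodes:
            continue
        if len(nodes) < n_requested:
            raise ValueError(
                f"{len(nodes)} {cls} node(s) cannot cover {n_requested} "
                "requested splits without leakage"
            )
        rng.shuffle(nodes)
        counts = _allocate(len(nodes), fractions)
        start = 0
        for name, count in zip(names, counts):
            for node in nodes[start:start + count]:
                split.group_map[node] = name
                getattr(split, name).extend(by_node[node])
            start += count
    return split
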