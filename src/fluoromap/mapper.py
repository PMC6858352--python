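"""Dense binary prediction maps by mirror-padded sliding-window classification.

The frame is reflected by half a window (139 px for the canonical 278 px
window) on all four sides, a window is slid over the padded frame at a fixed
step, each window is normalized and classified, the probability is binarized,
and the bit is assigned to the map pixel corresponding to the window center.

Geometry conventions
--------------------
* Window positions per axis follow the inclusive fencepost count
  ``floor((L_padded - patch) / step) + 1``.  For the canonical frame
  (2,592 x 2,048, pad 139, step 10) this yields a 205 x 260 grid — 53,300
  windows.  A ``truncate`` convention (``floor((L_padded - patch)/step)``,
  giving 204 x 259) is provided for comparison only.
* The "center" of the even-sized window is the upper-left pixel of its
  central 2 x 2 block, i.e. offset ``patch_size // 2`` from the window's
  top-left corner.  With ``pad == patch_size // 2`` the center of map pixel
  (r, c) falls on original-image coordinate ``(r * step, c * step)``, so map
  centers span the original frame.
* Reflection excludes the edge pixel (``numpy.pad`` ``reflect`` mode).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._integral import box_sums
from .patches import is_tumor_positive, normalize_patch
from .synthetic import LabeledImage

__all__ = [
    "MapperConfig",
    "PredictionMap",
    "mirror_pad",
    "grid_shape",
    "window_starts",
    "window_tumor_fraction_grid",
    "ground_truth_grid",
    "ground_truth_map",
    "build_map",
]

FENCEPOST = "fencepost"
TRUNCATE = "truncate"


@dataclass(frozen=True)
class MapperConfig:
    """Sliding-window geometry and binarization threshold."""

    patch_size: int = 278
    step: int = 10
    decision_threshold: float = 0.5
    convention: str = FENCEPOST

    def __post_init__(self) -> None:
        if self.patch_size < 2 or self.patch_size % 2:
            raise ValueError("patch_size must be even and >= 2")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if not 0.0 <= self.decision_threshold <= 1.0:
            raise ValueError("decision_threshold must be in [0, 1]")
        if self.convention not in (FENCEPOST, TRUNCATE):
            raise ValueError(f"unknown grid convention {self.convention!r}")

    @property
    def pad(self) -> int:
        """Mirror-pad width: half the window (139 for the 278 px window)."""
        return self.patch_size // 2


@dataclass
class PredictionMap:
    """Binary grid of per-window calls with geometry metadata.

    ``grid[r, c]`` is the call for the window centered at original-image
    coordinate ``(center_origin + r * step, center_origin + c * step)``.
    """

    grid: np.ndarray
    step: int
    patch_size: int
    pad: int
    source_shape: tuple[int, int]
    convention: str = FENCEPOST

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.uint8)
        if not np.isin(self.grid, (0, 1)).all():
            raise ValueError("grid entries must be 0/1")

    @property
    def center_origin(self) -> int:
        """Original-image coordinate of map pixel (0, 0)'s window center."""
        return self.patch_size // 2 - self.pad

    def center_coords(self, row: int, col: int) -> tuple[int, int]:
        """Original-image (y, x) of the window center for a map pixel."""
        return (self.center_origin + row * self.step,
                self.center_origin + col * self.step)

    @property
    def n_predictions(self) -> int:
        return int(self.grid.size)

    def save(self, png_path: str | Path) -> None:
        """Write the grid as a 0/255 PNG plus a JSON geometry sidecar."""
        import imageio.v3 as iio

        png_path = Path(png_path)
        iio.imwrite(png_path, self.grid * np.uint8(255))
        meta = {
            "step": self.step,
            "patch_size": self.patch_size,
            "pad": self.pad,
            "source_shape": list(self.source_shape),
            "convention": self.convention,
            "center_origin": self.center_origin,
        }
        png_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, png_path: str | Path) -> "PredictionMap":
        import imageio.v3 as iio

        png_path = Path(png_path)
        meta = json.loads(png_path.with_suffix(".json").read_text())
        grid = (np.asarray(iio.imread(png_path)) > 127).astype(np.uint8)
        return cls(grid=grid, step=meta["step"],
                   patch_size=meta["patch_size"], pad=meta["pad"],
                   source_shape=tuple(meta["source_shape"]),
                   convention=meta["convention"])


def mirror_pad(image: np.ndarray, pad: int) -> np.ndarray:
    """Reflect an array by ``pad`` pixels on all four sides.

    The reflection excludes the edge pixel (a row ``[1, 2, 3]`` padded by 2
    becomes ``[3, 2, 1, 2, 3, 2, 1]``); the interior equals the input.
    """
    image = np.asarray(image)
    if pad < 0:
        raise ValueError("pad must be non-negative")
    if pad == 0:
        return image.copy()
    if pad > min(image.shape[0], image.shape[1]) - 1:
        raise ValueError(
            f"pad {pad} too large for image of shape {image.shape[:2]} "
            "(reflection requires pad <= dim - 1)"
        )
    widths = [(pad, pad), (pad, pad)] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, widths, mode="reflect")


def grid_shape(length: int, patch_size: int, step: int,
               convention: str = FENCEPOST) -> int:
    """Number of window positions along one padded axis.

    The canonical convention is the inclusive fencepost count
    ``floor((length - patch_size)/step) + 1`` (window starts at 0, step,
    2*step, ...).  ``truncate`` drops the final fencepost and exists only to
    reproduce the alternative count for comparison.
    """
    if length < patch_size:
        raise ValueError(f"length {length} smaller than window {patch_size}")
    base = (length - patch_size) // step
    if convention == FENCEPOST:
        return base + 1
    if convention == TRUNCATE:
        return base
    raise ValueError(f"unknown grid convention {convention!r}")


def window_starts(padded_length: int, patch_size: int, step: int,
                  convention: str = FENCEPOST) -> np.ndarray:
    """Top-left coordinates of all windows along one padded axis."""
    n = grid_shape(padded_length, patch_size, step, convention)
    return np.arange(n) * step


def window_tumor_fraction_grid(mask: np.ndarray,
                               config: MapperConfig) -> np.ndarray:
    """Tumor fraction of every sliding window, on the map grid.

    The mask is mirror-padded with the same geometry as the frame; each
    window's fraction is (positive pixels in window) / patch_size**2,
    computed exactly with an integral image.
    """
    padded = mirror_pad(np.asarray(mask, dtype=np.uint8), config.pad)
    rows = window_starts(padded.shape[0], config.patch_size, config.step,
                         config.convention)
    cols = window_starts(padded.shape[1], config.patch_size, config.step,
                         config.convention)
    counts = box_sums(padded, config.patch_size, rows, cols)
    return counts / float(config.patch_size ** 2)


def ground_truth_grid(mask: np.ndarray, config: MapperConfig,
                      min_tumor_fraction: float = 0.0) -> np.ndarray:
    """Binary grid of per-window ground-truth labels (same rule as patches)."""
    frac = window_tumor_fraction_grid(mask, config)
    positive = (frac > 0) & (frac >= min_tumor_fraction)
    return positive.astype(np.uint8)


def ground_truth_map(image: LabeledImage, config: MapperConfig,
                     min_tumor_fraction: float = 0.0) -> PredictionMap:
    """Reference map labeled from the mask with :func:`build_map` geometry."""
    return PredictionMap(
        grid=ground_truth_grid(image.mask, config, min_tumor_fraction),
        step=config.step, patch_size=config.patch_size, pad=config.pad,
        source_shape=image.shape, convention=config.convention,
    )


def build_map(image: LabeledImage, classifier, config: MapperConfig,
              min_tumor_fraction: float = 0.0, *, use_fast_path: bool = True,
              batch_size: int = 32) -> PredictionMap:
    """Classify every sliding window of a mirror-padded frame.

    Each window is normalized (same scalar-max rule as training patches),
    classified, binarized at ``config.decision_threshold`` (probability >=
    threshold is positive), and stored at its grid index.

    Classifiers exposing ``predict_map_grid`` (the grid-aware oracles) are
    dispatched to their vectorized path unless ``use_fast_path=False``;
    pixel-free classifiers (``needs_pixels = False``) skip window
    extraction.  Classifier failures are re-raised with the offending window
    position attached.
    """
    if use_fast_path and hasattr(classifier, "predict_map_grid"):
        grid = classifier.predict_map_grid(image, config, min_tumor_fraction)
        return PredictionMap(grid=grid, step=config.step,
                             patch_size=config.patch_size, pad=config.pad,
                             source_shape=image.shape,
                             convention=config.convention)

    padded = mirror_pad(image.rgb, config.pad)
    rows = window_starts(padded.shape[0], config.patch_size, config.step,
                         config.convention)
    cols = window_starts(padded.shape[1], config.patch_size, config.step,
                         config.convention)
    if hasattr(classifier, "begin_image"):
        classifier.begin_image(image, config, min_tumor_fraction)

    needs_pixels = getattr(classifier, "needs_pixels", True)
    grid = np.zeros((len(rows), len(cols)), dtype=np.uint8)
    positions = [(r, c) for r in range(len(rows)) for c in range(len(cols))]
    ps = config.patch_size

    def classify(idx_pairs) -> None:
        probs = np.empty(len(idx_pairs))
        if needs_pixels and len(idx_pairs) > 1:
            windows = [
                normalize_patch(padded[rows[r]:rows[r] + ps,
                                       cols[c]:cols[c] + ps])
                for r, c in idx_pairs
            ]
            probs[:] = classifier.predict_proba_batch(windows)
        else:
            for k, (r, c) in enumerate(idx_pairs):
                window = None
                if needs_pixels:
                    window = normalize_patch(
                        padded[rows[r]:rows[r] + ps, cols[c]:cols[c] + ps])
                probs[k] = classifier.predict_proba(
                    window, pos=(int(rows[r]), int(cols[c])))
        for k, (r, c) in enumerate(idx_pairs):
            if not 0.0 <= probs[k] <= 1.0:
                raise ValueError(
                    f"classifier output {probs[k]} outside [0, 1] at window "
                    f"start ({rows[r]}, {cols[c]})"
                )
            grid[r, c] = 1 if probs[k] >= config.decision_threshold else 0

    for start in range(0, len(positions), batch_size):
        chunk = positions[start:start + batch_size]
        try:
            classify(chunk)
        except Exception as err:
            r, c = chunk[0]
            raise RuntimeError(
                f"classification failed in window batch starting at grid "
                f"({r}, {c}), padded start ({rows[r]}, {cols[c]})"
            ) from err

    return PredictionMap(grid=grid, step=config.step,
                         patch_size=config.patch_size, pad=config.pad,
                         source_shape=image.shape,
                         convention=config.convention)
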