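"""Position-keyed noisy oracle over a frame's ground-truth mask.

The oracle knows each window's true label (the same tumor-presence rule as
patch labeling, applied to the window footprint on the mirror-padded mask)
and flips it with configurable false-positive / false-negative rates.  The
flip for a window depends only on ``(seed, window position)`` through a
counter-based hash, so the per-window path and the vectorized whole-grid
path agree bit for bit and repeated calls are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import mapper as _mapper
from ..synthetic import LabeledImage
from .base import PatchClassifier

__all__ = ["NoisyOracleConfig", "NoisyOracleClassifier", "noisy_oracle"]

_M1 = np.uint64(0x9E3779B97F4A7C15)
_M2 = np.uint64(0xC2B2AE3D27D4EB4F)
_M3 = np.uint64(0xBF58476D1CE4E5B9)
_M4 = np.uint64(0x94D049BB133111EB)


def position_uniform(seed: int, rows: np.ndarray,
                     cols: np.ndarray) -> np.ndarray:
    """Deterministic uniform(0, 1) draw keyed on (seed, row, col).

    splitmix64-style finalizer on a linear combination of the key; vectorized
    and stateless, so any evaluation order yields the same draws.
    """
    rows = np.asarray(rows, dtype=np.uint64)
    cols = np.asarray(cols, dtype=np.uint64)
    with np.errstate(over="ignore"):
        z = (np.uint64(seed & 0xFFFFFFFFFFFFFFFF)
             + rows * _M1 + cols * _M2 + _M1)
        z = (z ^ (z >> np.uint64(30))) * _M3
        z = (z ^ (z >> np.uint64(27))) * _M4
        z = z ^ (z >> np.uint64(31))
    return z.astype(np.float64) / float(2 ** 64)


@dataclass(frozen=True)
class NoisyOracleConfig:
    """Error model: independent per-window flip rates."""

    fp_rate: float = 0.0
    fn_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fp_rate <= 1.0 and 0.0 <= self.fn_rate <= 1.0):
            raise ValueError("fp_rate and fn_rate must be in [0, 1]")


class NoisyOracleClassifier(PatchClassifier):
    """Ground-truth window classifier with independent flip noise.

    Bound to one :class:`LabeledImage`.  Emits probability 1.0 or 0.0: the
    window's true label flipped with ``fp_rate`` (negatives) or ``fn_rate``
    (positives).  Requires the window position; pixels are ignored
    (``needs_pixels = False``).
    """

    needs_pixels = False

    def __init__(self, image: LabeledImage, config: NoisyOracleConfig):
        self.image = image
        self.config = config
        self._padded_mask: np.ndarray | None = None
        self._geom: tuple[int, int, float] | None = None

    # -- mapper hooks -------------------------------------------------------

    def begin_image(self, image: LabeledImage, config: "_mapper.MapperConfig",
                    min_tumor_fraction: float) -> None:
        """Bind sliding-window geometry before per-window queries."""
        self._check_image(image)
        self._padded_mask = _mapper.mirror_pad(
            self.image.mask.astype(np.uint8), config.pad)
        self._geom = (config.pad, config.patch_size, min_tumor_fraction)

    def predict_proba(self, patch=None, pos: tuple[int, int] | None = None
                      ) -> float:
        if pos is None:
            raise ValueError("the noisy oracle requires a window position")
        if self._padded_mask is None or self._geom is None:
            raise RuntimeError("begin_image() must be called before "
                               "per-window oracle queries")
        _, patch_size, min_frac = self._geom
        r0, c0 = pos
        window = self._padded_mask[r0:r0 + patch_size, c0:c0 + patch_size]
        frac = float(window.sum()) / (patch_size ** 2)
        truth = frac > 0 and frac >= min_frac
        u = float(position_uniform(self.config.seed,
                                   np.uint64(r0), np.uint64(c0)))
        if truth:
            return 0.0 if u < self.config.fn_rate else 1.0
        return 1.0 if u < self.config.fp_rate else 0.0

    def predict_map_grid(self, image: LabeledImage,
                         config: "_mapper.MapperConfig",
                         min_tumor_fraction: float = 0.0) -> np.ndarray:
        """Vectorized whole-grid prediction (bit-identical to the loop)."""
        self._check_image(image)
        truth = _mapper.ground_truth_grid(self.image.mask, config,
                                          min_tumor_fraction).astype(bool)
        padded_h = self.image.mask.shape[0] + 2 * config.pad
        padded_w = self.image.mask.shape[1] + 2 * config.pad
        rows = _mapper.window_starts(padded_h, config.patch_size, config.step,
                                     config.convention)
        cols = _mapper.window_starts(padded_w, config.patch_size, config.step,
                                     config.convention)
        u = position_uniform(self.config.seed, rows[:, None], cols[None, :])
        pred = np.where(truth, u >= self.config.fn_rate, u < self.config.fp_rate)
        return pred.astype(np.uint8)

    def _check_image(self, image: LabeledImage) -> None:
        if image is not self.image and not np.array_equal(image.mask,
                                                          self.image.mask):
            raise ValueError("oracle is bound to a different image")


def noisy_oracle(image: LabeledImage,
                 config: NoisyOracleConfig) -> NoisyOracleClassifier:
    """Build a noisy ground-truth classifier bound to one image."""
    if image.mask is None:
        raise ValueError("image has no mask")
    return NoisyOracleClassifier(image, config)
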