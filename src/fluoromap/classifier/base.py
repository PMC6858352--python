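"""The pluggable patch-classifier contract."""

from __future__ import annotations

import abc

import numpy as np

__all__ = ["PatchClassifier", "ConstantClassifier"]


class PatchClassifier(abc.ABC):
    """Maps one RGB patch to a metastasis-positive probability in [0, 1].

    Implementations must be deterministic given fixed trained state and
    input.  ``pos`` carries the window's top-left pixel coordinate in the
    padded frame when called from the sliding-window mapper; image-agnostic
    classifiers ignore it, position-keyed oracles require it.

    ``needs_pixels`` may be set to False by implementations that classify
    from position alone; the mapper then skips window extraction.
    """

    needs_pixels: bool = True

    @abc.abstractmethod
    def predict_proba(self, patch: np.ndarray | None,
                      pos: tuple[int, int] | None = None) -> float:
        """Return the positive-class probability for one patch."""

    def predict_proba_batch(self, patches: list[np.ndarray]) -> np.ndarray:
        """Vectorized hook; the default just loops."""
        return np.array([self.predict_proba(p) for p in patches])

    def fit(self, train, validation):  # pragma: no cover - optional
        raise NotImplementedError(
            f"{type(self).__name__} does not support fitting"
        )


class ConstantClassifier(PatchClassifier):
    """Emits a fixed probability regardless of input (testing aid)."""

    needs_pixels = False

    def __init__(self, probability: float):
        if not 0.0 <= probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        self.probability = float(probability)

    def predict_proba(self, patch=None, pos=None) -> float:
        return self.probability
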