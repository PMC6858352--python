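import numpy as np
import pytest

from fluoromap.synthetic import SceneSpec, Status, LabeledImage, generate_image


@pytest.fixture(scope="session")
def small_spec() -> SceneSpec:
    return SceneSpec(width=220, height=180, n_lesions=1,
                     lesion_diameter_range=(30.0, 40.0),
                     lymphocyte_density=20.0, seed=11)


@pytest.fixture(scope="session")
def small_positive_image(small_spec) -> LabeledImage:
    return generate_image(small_spec)


@pytest.fixture(scope="session")
def small_negative_image(small_spec) -> LabeledImage:
    from dataclasses import replace

    return generate_image(replace(small_spec, n_lesions=0, seed=12))


def make_blank_image(h: int, w: int, mask: np.ndarray | None = None
                     ) -> LabeledImage:
    """All-black frame with an optional mask (geometry-only tests)."""
    if mask is None:
        mask = np.zeros((h, w), dtype=bool)
    status = Status.POSITIVE if mask.any() else Status.NEGATIVE
    return LabeledImage(rgb=np.zeros((h, w, 3), dtype=np.uint8),
                        mask=mask.astype(bool), status=status)
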