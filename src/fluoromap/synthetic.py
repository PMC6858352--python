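"""Synthetic pseudo-fluorescence lymph-node images with ground-truth masks.

Images imitate two-channel nucleic-acid fluorescence microscopy: dense small
blue lymphocyte nuclei as background, metastatic lesions built from larger
cells with green cytoplasm, enlarged blue nuclei and bright green nucleoli,
and histiocyte nodules as confounders (green cytoplasm, intermediate nuclei,
no nucleoli, never part of the tumor mask).

Rendering is parametric-geometric: soft-edged discs composited by maximum
blending, followed by a multiplicative illumination gradient and additive
Gaussian noise.  Identical :class:`SceneSpec` values (including ``seed``)
produce bit-identical rasters.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LesionPattern",
    "Status",
    "SceneSpec",
    "LabeledImage",
    "PlacementError",
    "generate_image",
    "generate_dataset",
    "write_dataset",
    "read_manifest",
]

# Morphological scale defaults (micrometres).  The confounder nucleus is
# deliberately intermediate between lymphocyte and lesion-cell nuclei.
LYMPHOCYTE_NUCLEUS_UM = 7.0
LESION_NUCLEUS_UM = 12.0
HISTIOCYTE_NUCLEUS_UM = 10.0

_PLACEMENT_RETRIES = 1000


class LesionPattern(str, enum.Enum):
    """Architectural growth pattern used to arrange lesion cells."""

    GLANDULAR = "glandular"
    CRIBRIFORM = "cribriform"
    SOLID = "solid"


class Status(str, enum.Enum):
    """Per-image metastasis status."""

    POSITIVE = "positive"
    NEGATIVE = "negative"


class PlacementError(RuntimeError):
    """Raised when non-overlapping placement fails after bounded retries.

    Distinct from ``ValueError`` so that an over-constrained (but formally
    valid) scene can be told apart from an invalid one.
    """


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Parameters
    ----------
    width, height : int
        Frame size in pixels.
    pixel_size : float
        Sampling pitch in micrometres per pixel.
    n_lesions : int
        Number of non-overlapping metastatic lesions to render.
    lesion_diameter_range : tuple of float
        Min/max lesion footprint diameter in micrometres.
    lesion_pattern : LesionPattern
        Cell arrangement inside each lesion footprint.
    n_histiocyte_nodules : int
        Number of confounder nodules (never included in the mask).
    lymphocyte_density : float
        Lymphocyte nuclei per 100 x 100 um of background.
    noise_sd : float
        Standard deviation of additive Gaussian noise, as a fraction of the
        full intensity scale.
    illumination_gradient : float
        Fractional peak-to-peak range of a linear multiplicative shading
        field (0 = flat illumination).
    seed : int
        RNG seed; equal specs produce bit-identical rasters.
    """

    width: int = 2592
    height: int = 2048
    pixel_size: float = 0.46
    n_lesions: int = 1
    lesion_diameter_range: tuple[float, float] = (55.0, 160.0)
    lesion_pattern: LesionPattern = LesionPattern.SOLID
    n_histiocyte_nodules: int = 0
    lymphocyte_density: float = 25.0
    noise_sd: float = 0.02
    illumination_gradient: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_lesions < 0 or self.n_histiocyte_nodules < 0:
            raise ValueError("counts must be non-negative")
        lo, hi = self.lesion_diameter_range
        if lo > hi:
            raise ValueError("lesion_diameter_range must be (min, max)")
        if lo < 2 * LYMPHOCYTE_NUCLEUS_UM:
            raise ValueError(
                "minimum lesion diameter must be at least twice the "
                f"lymphocyte nucleus diameter ({2 * LYMPHOCYTE_NUCLEUS_UM} um)"
            )
        if self.lymphocyte_density < 0 or self.noise_sd < 0:
            raise ValueError("densities and noise_sd must be non-negative")
        if not isinstance(self.lesion_pattern, LesionPattern):
            object.__setattr__(
                self, "lesion_pattern", LesionPattern(self.lesion_pattern)
            )


@dataclass
class LabeledImage:
    """An RGB frame with its binary tumor mask and provenance.

    Attributes
    ----------
    rgb : ndarray of uint8, shape (H, W, 3)
    mask : ndarray of bool, shape (H, W)
        True where a metastatic lesion footprint was rendered.
    node_id : str
        Opaque grouping key (all frames of one node share it).
    status : Status
        ``POSITIVE`` iff the mask has at least one foreground pixel.
    """

    rgb: np.ndarray
    mask: np.ndarray
    node_id: str = "node"
    status: Status = Status.NEGATIVE

    def __post_init__(self) -> None:
        if self.rgb.shape[:2] != self.mask.shape:
            raise ValueError("rgb and mask dimensions differ")
        has_tumor = bool(self.mask.any())
        expected = Status.POSITIVE if has_tumor else Status.NEGATIVE
        if self.status != expected:
            raise ValueError(
                f"status {self.status.value!r} inconsistent with mask "
                f"({'non-empty' if has_tumor else 'empty'})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _paint_disc(img: np.ndarray, cy: float, cx: float, radius: float,
                color: Sequence[float], edge: float = 1.5) -> None:
    """Max-blend a soft-edged disc of the given color onto a float image."""
    h, w = img.shape[:2]
    r_out = radius + edge
    y0, y1 = max(0, int(cy - r_out)), min(h, int(cy + r_out) + 2)
    x0, x1 = max(0, int(cx - r_out)), min(w, int(cx + r_out) + 2)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(yy - cy, xx - cx)
    alpha = np.clip((radius - dist) / edge + 1.0, 0.0, 1.0)
    region = img[y0:y1, x0:x1]
    np.maximum(region, alpha[..., None] * np.asarray(color), out=region)


def _paint_cell(img: np.ndarray, rng: np.random.Generator, cy: float,
                cx: float, nucleus_r: float, *, cytoplasm: bool,
                nucleolus: bool) -> None:
    """Render one cell: optional green cytoplasm, blue nucleus, nucleolus."""
    if cytoplasm:
        cyto_r = nucleus_r * rng.uniform(1.5, 1.8)
        green = rng.uniform(0.50, 0.62)
        _paint_disc(img, cy, cx, cyto_r, (0.08, green, 0.10))
    blue = rng.uniform(0.65, 0.85)
    _paint_disc(img, cy, cx, nucleus_r, (0.05, 0.13, blue))
    if nucleolus:
        # bright green dot inside the nucleus
        off = nucleus_r * 0.35
        ncy = cy + rng.uniform(-off, off)
        ncx = cx + rng.uniform(-off, off)
        _paint_disc(img, ncy, ncx, nucleus_r * 0.28,
                    (0.15, rng.uniform(0.85, 0.95), 0.35), edge=1.0)


def _jittered_grid(rng: np.random.Generator, radius: float, spacing: float,
                   jitter: float) -> list[tuple[float, float]]:
    """Hex-ish jittered grid of points inside a circle of ``radius``."""
    pts = []
    n = int(math.ceil(radius / spacing))
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            y = i * spacing + (spacing / 2 if j % 2 else 0.0)
            x = j * spacing * 0.87
            y += rng.uniform(-jitter, jitter)
            x += rng.uniform(-jitter, jitter)
            if math.hypot(y, x) <= radius:
                pts.append((y, x))
    return pts


def _render_lesion(img: np.ndarray, rng: np.random.Generator, cy: float,
                   cx: float, radius: float, pattern: LesionPattern,
                   pixel_size: float) -> None:
    """Arrange lesion cells inside a circular footprint."""
    nucleus_r = LESION_NUCLEUS_UM / pixel_size / 2
    cell_spacing = nucleus_r * 2.4
    inner = max(radius - nucleus_r, nucleus_r)

    if pattern is LesionPattern.SOLID:
        pts = _jittered_grid(rng, inner, cell_spacing, nucleus_r * 0.3)
    elif pattern is LesionPattern.CRIBRIFORM:
        pts = _jittered_grid(rng, inner, cell_spacing, nucleus_r * 0.3)
        # punch round lumina out of the solid sheet
        n_holes = max(1, int(radius / (4 * nucleus_r)))
        holes = [(rng.uniform(-inner, inner), rng.uniform(-inner, inner),
                  rng.uniform(1.2, 2.0) * nucleus_r) for _ in range(n_holes)]
        pts = [
            (y, x) for y, x in pts
            if all(math.hypot(y - hy, x - hx) > hr + nucleus_r
                   for hy, hx, hr in holes)
        ]
    else:  # glandular: rings of cells around empty lumina
        pts = []
        n_rings = max(1, int(inner / (2.5 * cell_spacing)))
        for _ in range(n_rings * 2):
            ring_r = rng.uniform(1.2, 2.2) * cell_spacing
            gy = rng.uniform(-1, 1) * max(inner - ring_r, 0)
            gx = rng.uniform(-1, 1) * max(inner - ring_r, 0)
            n_cells = max(5, int(2 * math.pi * ring_r / (nucleus_r * 2.2)))
            for k in range(n_cells):
                ang = 2 * math.pi * k / n_cells + rng.uniform(-0.1, 0.1)
                y = gy + ring_r * math.cos(ang)
                x = gx + ring_r * math.sin(ang)
                if math.hypot(y, x) <= inner:
                    pts.append((y, x))

    if not pts:  # footprint smaller than one cell spacing: single cell
        pts = [(0.0, 0.0)]
    for y, x in pts:
        _paint_cell(img, rng, cy + y, cx + x, nucleus_r,
                    cytoplasm=True, nucleolus=True)


def _render_histiocyte_nodule(img: np.ndarray, rng: np.random.Generator,
                              cy: float, cx: float, radius: float,
                              pixel_size: float) -> None:
    nucleus_r = HISTIOCYTE_NUCLEUS_UM / pixel_size / 2
    inner = max(radius - nucleus_r, nucleus_r)
    pts = _jittered_grid(rng, inner, nucleus_r * 2.6, nucleus_r * 0.4)
    if not pts:
        pts = [(0.0, 0.0)]
    for y, x in pts:
        _paint_cell(img, rng, cy + y, cx + x, nucleus_r,
                    cytoplasm=True, nucleolus=False)


def _place_circles(rng: np.random.Generator, h: int, w: int,
                   radii: Sequence[float],
                   occupied: list[tuple[float, float, float]]) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping circle centers fully inside the frame."""
    placed: list[tuple[float, float, float]] = []
    for r in radii:
        if 2 * r >= min(h, w):
            raise PlacementError(
                f"footprint of radius {r:.0f}px does not fit a {h}x{w} frame"
            )
        for _ in range(_PLACEMENT_RETRIES):
            cy = rng.uniform(r, h - r)
            cx = rng.uniform(r, w - r)
            if all(math.hypot(cy - oy, cx - ox) > r + orad
                   for oy, ox, orad in occupied + placed):
                placed.append((cy, cx, r))
                break
        else:
            raise PlacementError(
                f"could not place {len(radii)} non-overlapping footprints "
                f"after {_PLACEMENT_RETRIES} retries (frame {h}x{w})"
            )
    return placed


def _circle_mask(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def generate_image(spec: SceneSpec, node_id: str = "node") -> LabeledImage:
    """Render one labeled pseudo-fluorescence frame.

    The mask foreground is exactly the union of lesion footprint discs;
    histiocyte nodules contribute no mask pixels.

    Raises
    ------
    PlacementError
        If ``n_lesions`` + nodules cannot be placed without overlap within
        the bounded retry budget.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.zeros((h, w, 3), dtype=np.float64)
    img += np.array([0.02, 0.05, 0.03])  # faint background

    # footprints first so placement failure precedes any heavy rendering
    lo, hi = spec.lesion_diameter_range
    lesion_radii = [
        rng.uniform(lo, hi) / spec.pixel_size / 2 for _ in range(spec.n_lesions)
    ]
    lesions = _place_circles(rng, h, w, lesion_radii, [])
    nodule_radii = [
        rng.uniform(0.5, 0.9) * HISTIOCYTE_NUCLEUS_UM * 4 / spec.pixel_size
        for _ in range(spec.n_histiocyte_nodules)
    ]
    nodules = _place_circles(rng, h, w, nodule_radii, list(lesions))

    # background lymphocytes
    area_units = (h * w) * (spec.pixel_size / 100.0) ** 2
    n_lymph = rng.poisson(spec.lymphocyte_density * area_units)
    nucleus_r = LYMPHOCYTE_NUCLEUS_UM / spec.pixel_size / 2
    for _ in range(n_lymph):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        r = nucleus_r * rng.uniform(0.85, 1.15)
        _paint_disc(img, cy, cx, r,
                    (0.04, rng.uniform(0.08, 0.14), rng.uniform(0.6, 0.8)))

    mask = np.zeros((h, w), dtype=bool)
    for cy, cx, r in lesions:
        _render_lesion(img, rng, cy, cx, r, spec.lesion_pattern,
                       spec.pixel_size)
        mask |= _circle_mask(h, w, cy, cx, r)
    for cy, cx, r in nodules:
        _render_histiocyte_nodule(img, rng, cy, cx, r, spec.pixel_size)

    if spec.illumination_gradient:
        gx = np.linspace(-0.5, 0.5, w)
        gy = np.linspace(-0.5, 0.5, h)
        field = 1.0 + spec.illumination_gradient * (
            gy[:, None] * 0.5 + gx[None, :] * 0.5
        )
        img *= field[..., None]
    if spec.noise_sd:
        img += rng.normal(0.0, spec.noise_sd, img.shape)

    rgb = (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)
    status = Status.POSITIVE if mask.any() else Status.NEGATIVE
    return LabeledImage(rgb=rgb, mask=mask, node_id=node_id, status=status)


def _derive_seed(base_seed: int, index: int) -> int:
    """Deterministic per-image seed from (base_seed, image_index)."""
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0])


def generate_dataset(n_positive_images: int, n_negative_images: int,
                     nodes_per_class: int,
                     base_spec: SceneSpec) -> list[LabeledImage]:
    """Generate a labeled dataset with node-grouped provenance.

    Positive frames render ``max(base_spec.n_lesions, 1)`` lesions; negative
    frames render none (their nodules, if any, are kept as confounders).
    Node ids are assigned round-robin so every node contributes at least one
    image.  Per-image seeds derive deterministically from ``base_spec.seed``.
    """
    if n_positive_images < 1 or n_negative_images < 1:
        raise ValueError("need at least one image per class")
    if nodes_per_class < 1:
        raise ValueError("nodes_per_class must be >= 1")
    if nodes_per_class > min(n_positive_images, n_negative_images):
        raise ValueError("nodes_per_class exceeds images available per class")

    images: list[LabeledImage] = []
    index = 0
    for status, count in ((Status.POSITIVE, n_positive_images),
                          (Status.NEGATIVE, n_negative_images)):
        for i in range(count):
            node = f"{status.value[:3]}{i % nodes_per_class:03d}"
            n_lesions = max(base_spec.n_lesions, 1) \
                if status is Status.POSITIVE else 0
            spec = replace(base_spec, n_lesions=n_lesions,
                           seed=_derive_seed(base_spec.seed, index))
            images.append(generate_image(spec, node_id=node))
            index += 1
    return images


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------

def write_dataset(images: Iterable[LabeledImage], out_dir: str | Path) -> Path:
    """Write frames as 8-bit RGB PNG, masks as 0/255 PNG, plus a CSV manifest.

    Returns the manifest path.  Manifest columns: path, mask_path, node_id,
    status (paths relative to the manifest's directory).
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "mask_path", "node_id", "status"])
        for i, im in enumerate(images):
            name, mask_name = f"image_{i:04d}.png", f"mask_{i:04d}.png"
            iio.imwrite(out / name, im.rgb)
            iio.imwrite(out / mask_name,
                        (im.mask.astype(np.uint8) * 255))
            writer.writerow([name, mask_name, im.node_id, im.status.value])
    return manifest


def read_manifest(manifest_path: str | Path) -> list[LabeledImage]:
    """Load a dataset written by :func:`write_dataset`."""
    import imageio.v3 as iio

    base = Path(manifest_path).parent
    images = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            rgb = np.asarray(iio.imread(base / row["path"]))
            mask = np.asarray(iio.imread(base / row["mask_path"])) > 127
            images.append(LabeledImage(rgb=rgb, mask=mask,
                                       node_id=row["node_id"],
                                       status=Status(row["status"])))
    return images
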