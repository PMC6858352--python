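"""End-to-end orchestration: synthesize, patch, train, map, vote, report.

Also hosts the error-budget arithmetic and overlay rendering used when
inspecting mapping results.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifier import (NoisyOracleConfig, TrainConfig, noisy_oracle,
                         train_small_cnn)
from .majority import (PAPER_THRESHOLDS, EvaluationTable, MajorityConfig,
                       decide_image, majority_vote, threshold_sweep,
                       vote_window_for_step)
from .mapper import MapperConfig, PredictionMap, build_map
from .patches import EXCLUDED, extract_labeled_patches, split_by_node
from .synthetic import (LabeledImage, SceneSpec, Status, generate_dataset,
                        write_dataset)

logger = logging.getLogger(__name__)

__all__ = ["expected_error_count", "render_overlay", "RunConfig",
           "run_pipeline"]

PINK = np.array([255, 105, 180], dtype=np.float64)
GREEN = np.array([60, 200, 90], dtype=np.float64)


def expected_error_count(n_windows: int, accuracy: float) -> float:
    """Expected misclassified windows: ``n_windows * (1 - accuracy)``."""
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must be in [0, 1]")
    if n_windows < 0:
        raise ValueError("n_windows must be non-negative")
    return n_windows * (1.0 - accuracy)


def map_pixel_to_image(index: int, pmap: PredictionMap,
                       map_offset: int = 0) -> int:
    """Original-image coordinate of a (possibly cropped) map pixel center."""
    return pmap.center_origin + (index + map_offset) * pmap.step


def image_to_map_pixel(coord: int, pmap: PredictionMap,
                       map_offset: int = 0) -> int:
    """Nearest map pixel index for an original-image coordinate."""
    return round((coord - pmap.center_origin) / pmap.step) - map_offset


def render_overlay(rgb: np.ndarray, grid: np.ndarray, pmap: PredictionMap,
                   map_offset: int = 0, alpha: float = 0.4) -> np.ndarray:
    """Alpha-blend a binary map onto its source frame.

    Positive map pixels tint pink, negative green.  ``grid`` may be the raw
    map or a majority-filtered crop of it; ``map_offset`` is the raw-map
    index of the crop's (0, 0) pixel (``vote_window // 2`` to center a
    filtered map).  Image pixels outside the grid's footprint — e.g. the
    border removed by the vote — are left unblended.
    """
    rgb = np.asarray(rgb)
    grid = np.asarray(grid)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) frame")
    h, w = rgb.shape[:2]
    half = pmap.step / 2.0

    def nearest(coords: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
        centers0 = map_pixel_to_image(0, pmap, map_offset)
        rel = (coords - centers0) / pmap.step
        idx = np.round(rel).astype(int)
        covered = (coords >= centers0 - half) & \
            (coords <= map_pixel_to_image(n - 1, pmap, map_offset) + half)
        return np.clip(idx, 0, n - 1), covered

    iy, cy = nearest(np.arange(h), grid.shape[0])
    ix, cx = nearest(np.arange(w), grid.shape[1])
    labels = grid[np.ix_(iy, ix)]
    covered = cy[:, None] & cx[None, :]

    out = rgb.astype(np.float64)
    tint = np.where(labels[..., None] == 1, PINK, GREEN)
    blended = (1 - alpha) * out + alpha * tint
    out[covered] = blended[covered]
    return np.clip(out, 0, 255).round().astype(np.uint8)


@dataclass
class RunConfig:
    """One-document configuration of a full pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    scene: SceneSpec = field(default_factory=SceneSpec)
    n_train_pos: int = 6
    n_train_neg: int = 6
    n_eval_pos: int = 4
    n_eval_neg: int = 4
    nodes_per_class: int = 3
    classifier: str = "noisy_oracle"      # cnn | noisy_oracle | perfect_oracle
    fp_rate: float = 0.0
    fn_rate: float = 0.0
    train: TrainConfig = field(default_factory=TrainConfig)
    mapper: MapperConfig = field(default_factory=MapperConfig)
    thresholds: tuple[float, ...] = PAPER_THRESHOLDS
    min_tumor_fraction: float = 0.0
    split_fractions: tuple[float, float, float] = (0.7, 0.3, 0.0)
    render_overlays: bool = False

    def __post_init__(self) -> None:
        if self.classifier not in ("cnn", "noisy_oracle", "perfect_oracle"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        # the vote window must pair with the mapping step
        vote_window_for_step(self.mapper.step, self.mapper.patch_size)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "scene" in kwargs:
            scene = dict(kwargs["scene"])
            if "lesion_diameter_range" in scene:
                scene["lesion_diameter_range"] = tuple(
                    scene["lesion_diameter_range"])
            kwargs["scene"] = SceneSpec(**scene)
        if "train" in kwargs:
            kwargs["train"] = TrainConfig(**kwargs["train"])
        if "mapper" in kwargs:
            kwargs["mapper"] = MapperConfig(**kwargs["mapper"])
        for key in ("thresholds", "split_fractions"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _train_classifier(config: RunConfig, out: Path):
    base = replace(config.scene, seed=config.seed * 2 + 1)
    train_images = generate_dataset(config.n_train_pos, config.n_train_neg,
                                    config.nodes_per_class, base)
    write_dataset(train_images, out / "train_images")
    records = []
    for image in train_images:
        records.extend(extract_labeled_patches(
            image, config.mapper.patch_size, config.min_tumor_fraction))
    usable = [r for r in records if r.label != EXCLUDED]
    split = split_by_node(usable, config.split_fractions, seed=config.seed)
    train_cfg = replace(config.train, seed=config.seed)
    model = train_small_cnn(split.train, split.validation, train_cfg)
    model.save(out / "model.npz")
    return model


def run_pipeline(config: RunConfig) -> dict:
    """Run synthesize -> (train) -> map -> vote -> report; returns artifacts.

    All stage outputs are written under ``config.out_dir`` with
    deterministic names; rerunning with the same config and seed reproduces
    the decision table exactly (training is reproducible up to BLAS-order
    numerics).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()

    eval_base = replace(config.scene, seed=config.seed * 2)
    eval_images = generate_dataset(config.n_eval_pos, config.n_eval_neg,
                                   config.nodes_per_class, eval_base)
    manifest = write_dataset(eval_images, out / "eval_images")
    logger.info("stage synth: %d eval images (%.1fs)",
                len(eval_images), time.monotonic() - t0)

    model = None
    if config.classifier == "cnn":
        t = time.monotonic()
        try:
            model = _train_classifier(config, out)
        except Exception as err:
            raise RuntimeError("stage train failed") from err
        logger.info("stage train: done (%.1fs)", time.monotonic() - t)

    t = time.monotonic()
    maps: list[tuple[PredictionMap, Status]] = []
    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)
    for i, image in enumerate(eval_images):
        if model is not None:
            clf = model
        else:
            rates = (config.fp_rate, config.fn_rate) \
                if config.classifier == "noisy_oracle" else (0.0, 0.0)
            clf = noisy_oracle(image, NoisyOracleConfig(
                fp_rate=rates[0], fn_rate=rates[1],
                seed=config.seed * 1000 + i))
        try:
            pmap = build_map(image, clf, config.mapper,
                             config.min_tumor_fraction)
        except Exception as err:
            raise RuntimeError(f"stage map failed on image {i}") from err
        pmap.save(maps_dir / f"map_{i:04d}.png")
        maps.append((pmap, image.status))
    logger.info("stage map: %d maps (%.1fs)", len(maps),
                time.monotonic() - t)

    table = threshold_sweep(maps, config.thresholds)
    table.to_csv(out / "evaluation_table.csv")

    k = vote_window_for_step(config.mapper.step, config.mapper.patch_size)
    rows = []
    for i, ((pmap, status), image) in enumerate(zip(maps, eval_images)):
        row = {"image": f"image_{i:04d}", "node_id": image.node_id,
               "status": status.value,
               "call_none": decide_image(pmap.grid).image_call.value}
        for thr in config.thresholds:
            cfg = MajorityConfig(vote_window=k, threshold=thr)
            filtered = majority_vote(pmap, cfg)
            row[f"call_{thr:.2f}"] = decide_image(filtered).image_call.value
        rows.append(row)
        if config.render_overlays:
            import imageio.v3 as iio

            cfg = MajorityConfig(vote_window=k, threshold=0.7)
            overlay = render_overlay(image.rgb, majority_vote(pmap, cfg),
                                     pmap, map_offset=k // 2)
            iio.imwrite(out / f"overlay_{i:04d}.png", overlay)
    decisions = pd.DataFrame(rows)
    decisions.to_csv(out / "decisions.csv", index=False)

    report = {
        "seed": config.seed,
        "classifier": config.classifier,
        "n_eval_images": len(eval_images),
        "elapsed_s": round(time.monotonic() - t0, 2),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return {
        "manifest": manifest,
        "decisions": out / "decisions.csv",
        "evaluation_table": table,
        "maps_dir": maps_dir,
        "model": out / "model.npz" if model is not None else None,
    }
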