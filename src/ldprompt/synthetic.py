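"""Synthetic low-contrast shape scenes with instance masks and derived boxes.

Each scene contains one to a few smooth, deformable foreground blobs on a
darker background.  The boundary is genuinely ambiguous: the clean image is
Gaussian-blurred *before* pixel noise is added, so edge pixels carry
intermediate intensities, emulating the low-contrast, blurred-boundary regime
of medical structures.  Instances may touch, exercising the small/crowded
case.  Boxes are always derived from the masks via the same tight-box rule
used for real annotations, never drawn independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw

from .geometry import Box, mask_to_boxes

__all__ = ["SceneConfig", "SegSample", "generate_dataset", "split_dataset",
           "budget_subset"]

SHAPE_FAMILIES = ("ellipse", "perturbed-polygon", "smoothed-blob")
BUDGET_GRID = (0.1, 0.2, 0.5, 1.0)


@dataclass
class SceneConfig:
    """Generator settings; the defaults define the study conditions.

    64x64 images, 1-3 instances, foreground/background means 0.62/0.38,
    noise std 0.18, boundary blur radius 2.0 px: contrast is low enough and
    boundaries soft enough that an unprompted miniature model is imperfect
    and prompting has headroom.
    """

    image_size: int = 64
    min_instances: int = 1
    max_instances: int = 3
    shape_family: str = "smoothed-blob"
    fg_mean: float = 0.62
    bg_mean: float = 0.38
    noise_std: float = 0.18
    blur_radius: float = 2.0
    min_radius: float = 4.0
    max_radius: float = 10.0
    seed: int = field(default=None)  # mandatory

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("SceneConfig requires an explicit seed")
        if not (0 <= self.bg_mean <= 1 and 0 <= self.fg_mean <= 1):
            raise ValueError("intensity means must lie in [0, 1]")
        if self.shape_family not in SHAPE_FAMILIES:
            raise ValueError(f"unknown shape family {self.shape_family!r}")
        if self.min_instances < 1 or self.max_instances < self.min_instances:
            raise ValueError("need at least one instance per image")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "image_size", "min_instances", "max_instances", "shape_family",
            "fg_mean", "bg_mean", "noise_std", "blur_radius",
            "min_radius", "max_radius", "seed")}

    @staticmethod
    def from_dict(d: dict) -> "SceneConfig":
        return SceneConfig(**d)


@dataclass
class SegSample:
    """One scene: image, per-instance masks, their union, and derived boxes."""

    sample_id: str
    image: np.ndarray                    # (H, W) float in [0, 1]
    instance_masks: list[np.ndarray]     # each (H, W) bool
    boxes: list[Box]                     # one tight box per instance

    @property
    def union_mask(self) -> np.ndarray:
        out = np.zeros_like(self.instance_masks[0], dtype=bool)
        for m in self.instance_masks:
            out |= m
        return out


def _one_shape(rng: np.random.Generator, cfg: SceneConfig) -> np.ndarray:
    """Rasterize a single random shape as a boolean mask."""
    n = cfg.image_size
    r = rng.uniform(cfg.min_radius, cfg.max_radius)
    cy = rng.uniform(r + 1, n - r - 1)
    cx = rng.uniform(r + 1, n - r - 1)
    if cfg.shape_family == "ellipse":
        ry = r * rng.uniform(0.6, 1.0)
        rx = r * rng.uniform(0.6, 1.0)
        rot = rng.uniform(0, math.pi)
        rr, cc = draw.ellipse(cy, cx, ry, rx, shape=(n, n), rotation=rot)
    else:
        # radial polygon with low-order Fourier perturbation of the radius;
        # "smoothed-blob" additionally smooths the radius profile
        k = 24
        theta = np.linspace(0, 2 * math.pi, k, endpoint=False)
        amp = 0.25 if cfg.shape_family == "perturbed-polygon" else 0.35
        radii = r * (1.0 + amp * (
            rng.uniform(-1, 1) * np.cos(2 * theta + rng.uniform(0, math.pi))
            + 0.5 * rng.uniform(-1, 1) * np.cos(3 * theta + rng.uniform(0, math.pi))))
        if cfg.shape_family == "smoothed-blob":
            kernel = np.array([0.25, 0.5, 0.25])
            radii = np.convolve(np.pad(radii, 1, mode="wrap"), kernel, "valid")
        radii = np.clip(radii, 2.0, None)
        rr, cc = draw.polygon(cy + radii * np.sin(theta),
                              cx + radii * np.cos(theta), shape=(n, n))
    mask = np.zeros((n, n), dtype=bool)
    mask[rr, cc] = True
    return mask


def _render_scene(rng: np.random.Generator, cfg: SceneConfig,
                  sample_id: str) -> SegSample:
    n = cfg.image_size
    n_inst = int(rng.integers(cfg.min_instances, cfg.max_instances + 1))
    masks: list[np.ndarray] = []
    attempts = 0
    while len(masks) < n_inst:
        attempts += 1
        if attempts > 50 * cfg.max_instances:
            raise RuntimeError(
                "could not place the requested instances; the scene config "
                "is infeasible (shapes too large for the image)")
        cand = _one_shape(rng, cfg)
        if cand.sum() < 6:
            continue
        # instances may touch but not substantially overlap existing ones
        overlap = any((cand & m).sum() > 0.2 * min(cand.sum(), m.sum())
                      for m in masks)
        if overlap:
            continue
        for m in masks:  # carve earlier instances out of the newcomer
            cand &= ~m
        if cand.sum() < 6:
            continue
        masks.append(cand)
    union = np.zeros((n, n), dtype=bool)
    for m in masks:
        union |= m
    clean = np.where(union, cfg.fg_mean, cfg.bg_mean).astype(np.float64)
    if cfg.blur_radius > 0:  # blur before noise: edges become ambiguous
        clean = ndimage.gaussian_filter(clean, cfg.blur_radius)
    noisy = clean + rng.normal(0.0, cfg.noise_std, size=clean.shape)
    image = np.clip(noisy, 0.0, 1.0)
    boxes = [mask_to_boxes(m.astype(np.uint8))[0] for m in masks]
    return SegSample(sample_id=sample_id, image=image,
                     instance_masks=masks, boxes=boxes)


def generate_dataset(cfg: SceneConfig, n: int) -> list[SegSample]:
    """Deterministically generate `n` scenes from cfg.seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    return [_render_scene(rng, cfg, f"sample_{i:05d}") for i in range(n)]


def split_dataset(samples: list[SegSample], test_fraction: float,
                  val_fraction: float, seed: int = 2025):
    """Deterministic split: ids lexicographically sorted, shuffled once with
    the seeded generator, then partitioned into ceil(fraction*n)-sized test
    and validation sets with the remainder as train."""
    if not (0 < test_fraction < 1 and 0 < val_fraction < 1
            and test_fraction + val_fraction < 1):
        raise ValueError("fractions must lie in (0,1) and sum below 1")
    n = len(samples)
    n_test = math.ceil(test_fraction * n)
    n_val = math.ceil(val_fraction * n)
    if n_test + n_val >= n:
        raise ValueError("dataset too small for nonempty train split")
    by_id = {s.sample_id: s for s in samples}
    if len(by_id) != n:
        raise ValueError("sample ids must be unique")
    ids = sorted(by_id)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [ids[i] for i in order]
    test = [by_id[i] for i in shuffled[:n_test]]
    val = [by_id[i] for i in shuffled[n_test:n_test + n_val]]
    train = [by_id[i] for i in shuffled[n_test + n_val:]]
    return train, val, test


def budget_subset(train_samples: list[SegSample], fraction: float,
                  seed: int = 2025) -> list[SegSample]:
    """First ceil(fraction*n) ids of a seeded shuffle.

    Because every budget shares the same shuffled prefix, subsets are nested
    (10% of the data is contained in 20%, 20% in 50%, and so on), and the same
    subset supplies both the distillation boxes and the segmentation masks.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    n = len(train_samples)
    if fraction == 1.0:
        return list(train_samples)
    by_id = {s.sample_id: s for s in train_samples}
    ids = sorted(by_id)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    keep = [ids[i] for i in order[:math.ceil(fraction * n)]]
    return [by_id[i] for i in keep]
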