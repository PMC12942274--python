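"""Segmentation evaluation: overlap metrics, boundary distances, bootstrap CIs.

Conventions (the literature is not uniform, so they are fixed here and
tested): two empty masks are a perfect match (Dice = IoU = 1, HD = ASSD = 0);
an empty mask against a nonempty one scores 0 overlap and the boundary
distances return the image-diagonal sentinel.  Boundary pixels are foreground
pixels with at least one background pixel among their 8 neighbors (pixels on
the image border count as boundary); distances are Euclidean in pixels.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["dice", "iou_score", "accuracy", "boundary_pixels",
           "hausdorff", "assd", "bootstrap_ci"]


def _check_pair(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    for name, m in (("pred", pred), ("gt", gt)):
        if m.dtype != bool and not np.all(np.isin(np.unique(m), (0, 1))):
            raise ValueError(f"{name} mask must be binary")
    return pred.astype(bool), gt.astype(bool)


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    pred, gt = _check_pair(pred, gt)
    denom = pred.sum() + gt.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, gt).sum() / denom)


def iou_score(pred: np.ndarray, gt: np.ndarray) -> float:
    pred, gt = _check_pair(pred, gt)
    union = np.logical_or(pred, gt).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pred, gt).sum() / union)


def accuracy(pred: np.ndarray, gt: np.ndarray) -> float:
    pred, gt = _check_pair(pred, gt)
    return float((pred == gt).mean())


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """(n, 2) row/col coordinates of 8-connected boundary pixels."""
    mask = np.asarray(mask).astype(bool)
    padded = np.pad(mask, 1, constant_values=False)
    interior = np.ones_like(mask)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            interior &= padded[1 + dr:1 + dr + mask.shape[0],
                               1 + dc:1 + dc + mask.shape[1]]
    boundary = mask & ~interior
    return np.argwhere(boundary)


def _directed_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min-distance from each point of a to the set b."""
    tree = cKDTree(b)
    d, _ = tree.query(a)
    return np.asarray(d, dtype=np.float64)


def _boundary_setup(pred, gt, return_flag):
    pred, gt = _check_pair(pred, gt)
    diag = float(np.hypot(*pred.shape))
    if not pred.any() and not gt.any():
        return 0.0, False, None, None, diag
    if not pred.any() or not gt.any():
        return diag, True, None, None, diag
    return None, False, boundary_pixels(pred), boundary_pixels(gt), diag


def hausdorff(pred: np.ndarray, gt: np.ndarray, return_flag: bool = False):
    """Symmetric Hausdorff distance between 8-connected boundaries (pixels).

    One empty mask -> image-diagonal sentinel (flagged when return_flag)."""
    early, flag, bp, bg, _ = _boundary_setup(pred, gt, return_flag)
    if early is not None:
        return (early, flag) if return_flag else early
    value = float(max(_directed_distances(bp, bg).max(),
                      _directed_distances(bg, bp).max()))
    return (value, False) if return_flag else value


def assd(pred: np.ndarray, gt: np.ndarray, return_flag: bool = False):
    """Average symmetric surface distance: mean of the two directed mean
    boundary distances (pixels)."""
    early, flag, bp, bg, _ = _boundary_setup(pred, gt, return_flag)
    if early is not None:
        return (early, flag) if return_flag else early
    value = float(0.5 * (_directed_distances(bp, bg).mean()
                         + _directed_distances(bg, bp).mean()))
    return (value, False) if return_flag else value


def bootstrap_ci(scores, n_boot: int = 1000, seed: int = 0,
                 level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of per-case scores."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("need at least one score")
    if scores.size < 2:
        raise ValueError("need at least two cases for a bootstrap CI")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, scores.size, size=(n_boot, scores.size))
    means = scores[idx].mean(axis=1)
    lo = (1.0 - level) / 2.0
    return (float(np.percentile(means, 100 * lo)),
            float(np.percentile(means, 100 * (1 - lo))))
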