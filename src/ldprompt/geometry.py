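"""Boxes, DIoU, mask-to-box derivation, and edge-distribution decoding.

Coordinate convention: continuous image frame with the origin at the top-left
pixel *corner*, x rightward, y downward.  Pixel (row i, col j) occupies the
half-open cell [j, j+1) x [i, i+1), so a tight box around a single foreground
pixel is 1x1.  Boxes are (xmin, ymin, xmax, ymax) in these continuous
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax as _softmax
from skimage import measure

__all__ = [
    "Box", "EdgeDistribution", "AnchorPoint",
    "mask_to_boxes", "iou", "diou", "diou_matrix", "decode_edges",
]

EDGES = ("t", "b", "l", "r")


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in continuous pixel coordinates."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self):
        vals = (self.xmin, self.ymin, self.xmax, self.ymax)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"box coordinates must be finite, got {vals}")
        if self.xmin > self.xmax or self.ymin > self.ymax:
            raise ValueError(f"degenerate box ordering: {vals}")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.xmin + self.xmax), 0.5 * (self.ymin + self.ymax))

    def as_array(self) -> np.ndarray:
        return np.array([self.xmin, self.ymin, self.xmax, self.ymax])

    def to_record(self, image_id: str, instance_id: int) -> dict:
        return {"image_id": image_id, "instance_id": int(instance_id),
                "xmin": float(self.xmin), "ymin": float(self.ymin),
                "xmax": float(self.xmax), "ymax": float(self.ymax)}

    @staticmethod
    def from_record(rec: dict) -> "Box":
        return Box(rec["xmin"], rec["ymin"], rec["xmax"], rec["ymax"])


@dataclass
class EdgeDistribution:
    """Logits over discrete spatial bins for one box edge.

    `bin_width` is the pixel extent of one bin; decoding takes the softmax
    expectation of bin index times bin width.  `temperature` is used when the
    distribution enters a distillation loss, not for decoding.
    """

    logits: np.ndarray
    bin_width: float
    temperature: float = 1.0

    def __post_init__(self):
        self.logits = np.asarray(self.logits, dtype=np.float64)
        if self.logits.ndim != 1 or self.logits.size < 2:
            raise ValueError("edge logits must be a vector of length >= 2")
        if not np.all(np.isfinite(self.logits)):
            raise ValueError("edge logits must be finite")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def num_bins(self) -> int:
        return int(self.logits.size)

    def probs(self, temperature: float | None = None) -> np.ndarray:
        tau = self.temperature if temperature is None else temperature
        if tau <= 0:
            raise ValueError("temperature must be positive")
        return _softmax(self.logits / tau)

    def expected_distance(self) -> float:
        """E[index] * bin_width under the tau=1 softmax; nonnegative."""
        p = self.probs(temperature=1.0)
        return float(np.dot(p, np.arange(self.num_bins)) * self.bin_width)


@dataclass(frozen=True)
class AnchorPoint:
    """Per-location prediction site of the detection head."""

    cx: float
    cy: float
    stride: int

    def __post_init__(self):
        if self.stride not in (8, 16, 32):
            raise ValueError(f"stride must be one of 8/16/32, got {self.stride}")


def mask_to_boxes(mask: np.ndarray, connectivity: int = 8) -> list[Box]:
    """Tight axis-aligned boxes around each connected component of a binary mask.

    One box per component, spanning exactly the min/max foreground pixel
    coordinates (half-open cell convention, so a lone pixel gives a 1x1 box).
    Components are ordered row-major by their first foreground pixel.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    uniq = np.unique(mask)
    if mask.dtype != bool and not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"mask must be binary, found values {uniq[:10]}")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = mask.astype(bool)
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    boxes: list[tuple[int, Box]] = []
    for region in measure.regionprops(labels):
        rmin, cmin, rmax, cmax = region.bbox  # already half-open
        rows, cols = np.nonzero(labels == region.label)
        first = int(np.min(rows * mask.shape[1] + cols))
        boxes.append((first, Box(float(cmin), float(rmin), float(cmax), float(rmax))))
    boxes.sort(key=lambda t: t[0])
    return [b for _, b in boxes]


def iou(a: Box, b: Box) -> float:
    """Intersection over union; zero if either box has zero area."""
    iw = min(a.xmax, b.xmax) - max(a.xmin, b.xmin)
    ih = min(a.ymax, b.ymax) - max(a.ymin, b.ymin)
    inter = max(iw, 0.0) * max(ih, 0.0)
    union = a.area + b.area - inter
    if union <= 0.0:
        return 0.0
    return inter / union


def diou(a: Box, b: Box) -> float:
    """Distance-IoU: IoU minus squared center distance over squared diagonal
    of the smallest enclosing box.  Symmetric; equals IoU when centers
    coincide; in (-1, 1].  Both boxes degenerate at the same point -> 0.
    """
    acx, acy = a.center
    bcx, bcy = b.center
    d2 = (acx - bcx) ** 2 + (acy - bcy) ** 2
    cw = max(a.xmax, b.xmax) - min(a.xmin, b.xmin)
    ch = max(a.ymax, b.ymax) - min(a.ymin, b.ymin)
    c2 = cw ** 2 + ch ** 2
    if c2 == 0.0:
        return 0.0
    return iou(a, b) - d2 / c2


def diou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Vectorized DIoU between two (n,4) / (m,4) arrays of (xmin,ymin,xmax,ymax)."""
    a = np.asarray(boxes_a, dtype=np.float64)[:, None, :]
    b = np.asarray(boxes_b, dtype=np.float64)[None, :, :]
    iw = np.minimum(a[..., 2], b[..., 2]) - np.maximum(a[..., 0], b[..., 0])
    ih = np.minimum(a[..., 3], b[..., 3]) - np.maximum(a[..., 1], b[..., 1])
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    area_a = (a[..., 2] - a[..., 0]) * (a[..., 3] - a[..., 1])
    area_b = (b[..., 2] - b[..., 0]) * (b[..., 3] - b[..., 1])
    union = area_a + area_b - inter
    iou_v = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    d2 = (0.5 * (a[..., 0] + a[..., 2]) - 0.5 * (b[..., 0] + b[..., 2])) ** 2 \
        + (0.5 * (a[..., 1] + a[..., 3]) - 0.5 * (b[..., 1] + b[..., 3])) ** 2
    cw = np.maximum(a[..., 2], b[..., 2]) - np.minimum(a[..., 0], b[..., 0])
    ch = np.maximum(a[..., 3], b[..., 3]) - np.minimum(a[..., 1], b[..., 1])
    c2 = cw ** 2 + ch ** 2
    return np.where(c2 > 0, iou_v - d2 / np.where(c2 > 0, c2, 1.0), 0.0)


def decode_edges(dists: dict[str, EdgeDistribution] | list[EdgeDistribution],
                 anchor: AnchorPoint) -> Box:
    """Decode four edge distributions (t, b, l, r) into a box around an anchor.

    Per-edge distance is the softmax expectation of bin index x bin width
    (temperature 1); the box is (cx-dl, cy-dt, cx+dr, cy+db).
    """
    if isinstance(dists, dict):
        try:
            seq = [dists[e] for e in EDGES]
        except KeyError as exc:
            raise ValueError(f"missing edge {exc} (need t, b, l, r)") from exc
    else:
        seq = list(dists)
        if len(seq) != 4:
            raise ValueError("need exactly four edge distributions (t, b, l, r)")
    n_bins = {d.num_bins for d in seq}
    widths = {d.bin_width for d in seq}
    if len(n_bins) != 1:
        raise ValueError(f"bin counts differ across edges: {sorted(n_bins)}")
    if len(widths) != 1:
        raise ValueError(f"bin widths differ across edges: {sorted(widths)}")
    dt, db, dl, dr = (d.expected_distance() for d in seq)
    return Box(anchor.cx - dl, anchor.cy - dt, anchor.cx + dr, anchor.cy + db)
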