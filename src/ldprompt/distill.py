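"""Localization-distillation losses and valuable-localization-region selection.

The teacher's box-edge logits are softened with a generalized (tempered)
softmax and the student matches them under a KL divergence, summed over the
four box edges.  Distillation is restricted to two disjoint anchor sets: the
main region (anchors whose best DIoU against ground truth clears the positive
threshold alpha_pos) and the valuable localization region (VLR), the band
[gamma * alpha_pos, alpha_pos) just below it.  The total objective adds these
region-weighted sums to the detection loss.

KL (rather than cross-entropy) is used so the loss is exactly zero at
teacher-student equality; the two differ only by the teacher-entropy constant.
By default losses are rescaled by tau^2, the standard correction that keeps
gradient magnitude roughly temperature-independent; a config flag disables it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Box, EdgeDistribution, diou_matrix
from .nn import Tensor, log_softmax

__all__ = [
    "DistillConfig", "RegionAssignment",
    "generalized_softmax", "ld_loss", "kd_class_loss",
    "select_regions", "total_distill_loss",
    "tempered_kl_tensor", "ld_loss_tensor",
]


@dataclass
class DistillConfig:
    """Hyperparameters of the distillation objective.

    temperature: softening temperature tau (default 10).
    lambda_main / lambda_vlr: region weights (default 1.0 each).
    alpha_pos: positive DIoU threshold in (0, 1].
    gamma: VLR bandwidth factor in (0, 1]; gamma=1 gives an empty VLR.
    tau_square_rescale: multiply losses by tau^2 (default on).
    """

    temperature: float = 10.0
    lambda_main: float = 1.0
    lambda_vlr: float = 1.0
    alpha_pos: float = 0.7
    gamma: float = 0.5
    tau_square_rescale: bool = True

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must lie in (0, 1]")
        if not (0.0 < self.alpha_pos <= 1.0):
            raise ValueError("alpha_pos must lie in (0, 1]")
        if self.lambda_main < 0 or self.lambda_vlr < 0:
            raise ValueError("region weights must be nonnegative")

    def to_dict(self) -> dict:
        return {"temperature": self.temperature, "lambda_main": self.lambda_main,
                "lambda_vlr": self.lambda_vlr, "alpha_pos": self.alpha_pos,
                "gamma": self.gamma, "tau_square_rescale": self.tau_square_rescale}

    @staticmethod
    def from_dict(d: dict) -> "DistillConfig":
        return DistillConfig(**d)


@dataclass
class RegionAssignment:
    """Per-anchor best-DIoU scores and the disjoint main/VLR index sets."""

    scores: np.ndarray              # X_k, best DIoU per anchor (-1 sentinel if no gt)
    omega_main: np.ndarray          # indices with X_k >= alpha_pos
    omega_vlr: np.ndarray           # indices with gamma*alpha_pos <= X_k < alpha_pos
    matched_gt: np.ndarray          # argmax gt index per anchor (-1 if no gt)

    def __post_init__(self):
        if np.intersect1d(self.omega_main, self.omega_vlr).size:
            raise ValueError("main and VLR regions must be disjoint")


def generalized_softmax(z: np.ndarray, tau: float) -> np.ndarray:
    """Tempered softmax p_i = exp(z_i/tau) / sum_j exp(z_j/tau).

    Numerically stabilized by max subtraction; tau=1 recovers the standard
    softmax, tau>1 flattens the distribution.
    """
    if tau <= 0:
        raise ValueError("temperature must be > 0")
    z = np.asarray(z, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("logits must be finite")
    zz = z / tau
    zz = zz - zz.max(axis=-1, keepdims=True)
    e = np.exp(zz)
    return e / e.sum(axis=-1, keepdims=True)


def _tempered_kl(teacher_logits: np.ndarray, student_logits: np.ndarray,
                 tau: float) -> float:
    """KL(p_T || p_S) between tempered distributions, via log-softmax."""
    def logsm(z):
        zz = np.asarray(z, dtype=np.float64) / tau
        zz = zz - zz.max(axis=-1, keepdims=True)
        return zz - np.log(np.exp(zz).sum(axis=-1, keepdims=True))

    log_pt = logsm(teacher_logits)
    log_ps = logsm(student_logits)
    pt = np.exp(log_pt)
    return float(np.sum(pt * (log_pt - log_ps)))


def _edge_logit_stack(edges) -> tuple[np.ndarray, int]:
    """Accept 4 EdgeDistributions or a (4, B) array; return stacked logits."""
    if isinstance(edges, np.ndarray):
        arr = np.asarray(edges, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] != 4:
            raise ValueError("edge logit array must have shape (4, B)")
        return arr, arr.shape[1]
    seq = list(edges)
    if len(seq) != 4:
        raise ValueError("need exactly four edge distributions")
    bins = {d.num_bins for d in seq}
    if len(bins) != 1:
        raise ValueError(f"bin counts differ across edges: {sorted(bins)}")
    return np.stack([d.logits for d in seq]), bins.pop()


def ld_loss(student, teacher, cfg: DistillConfig) -> float:
    """Localization-distillation loss: sum over edges {t,b,l,r} of
    KL(teacher || student) at temperature cfg.temperature, optionally
    rescaled by tau^2.  Zero iff the tempered distributions agree on all
    four edges; always nonnegative.
    """
    s_logits, s_bins = _edge_logit_stack(student)
    t_logits, t_bins = _edge_logit_stack(teacher)
    if s_bins != t_bins:
        raise ValueError(f"student has {s_bins} bins, teacher has {t_bins}")
    tau = cfg.temperature
    total = sum(_tempered_kl(t_logits[e], s_logits[e], tau) for e in range(4))
    if cfg.tau_square_rescale:
        total *= tau ** 2
    return max(total, 0.0)


def kd_class_loss(student_logits: np.ndarray, teacher_logits: np.ndarray,
                  tau: float, tau_square_rescale: bool = True) -> float:
    """Conventional classification-logit distillation: tempered
    KL(teacher || student) on the class distributions."""
    s = np.asarray(student_logits, dtype=np.float64)
    t = np.asarray(teacher_logits, dtype=np.float64)
    if s.shape != t.shape:
        raise ValueError(f"class-count mismatch: {s.shape} vs {t.shape}")
    loss = _tempered_kl(t, s, tau)
    if tau_square_rescale:
        loss *= tau ** 2
    return max(loss, 0.0)


def select_regions(decoded_boxes: list[Box] | np.ndarray,
                   gt_boxes: list[Box] | np.ndarray,
                   cfg: DistillConfig) -> RegionAssignment:
    """Assign anchors to the main and valuable localization regions.

    X_k is the maximum DIoU between anchor k's decoded box and any ground
    truth box; main = {k : X_k >= alpha_pos}, VLR = {k : gamma*alpha_pos <=
    X_k < alpha_pos}.  Ties in the argmax go to the lowest gt index.  With no
    ground truth both sets are empty and X is the -1 sentinel.
    """
    dec = _boxes_to_array(decoded_boxes)
    if dec.shape[0] == 0:
        raise ValueError("anchors must be nonempty")
    gt = _boxes_to_array(gt_boxes)
    n = dec.shape[0]
    if gt.shape[0] == 0:
        return RegionAssignment(
            scores=np.full(n, -1.0), omega_main=np.empty(0, dtype=int),
            omega_vlr=np.empty(0, dtype=int), matched_gt=np.full(n, -1, dtype=int))
    scores_mat = diou_matrix(dec, gt)
    matched = scores_mat.argmax(axis=1)  # np.argmax takes the lowest index on ties
    x = scores_mat[np.arange(n), matched]
    main = np.flatnonzero(x >= cfg.alpha_pos)
    vlr = np.flatnonzero((x >= cfg.gamma * cfg.alpha_pos) & (x < cfg.alpha_pos))
    return RegionAssignment(scores=x, omega_main=main, omega_vlr=vlr,
                            matched_gt=matched.astype(int))


def _boxes_to_array(boxes) -> np.ndarray:
    if isinstance(boxes, np.ndarray):
        arr = np.asarray(boxes, dtype=np.float64)
        if arr.size == 0:
            return arr.reshape(0, 4)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError("box array must have shape (n, 4)")
        return arr
    if len(boxes) == 0:
        return np.empty((0, 4))
    return np.stack([b.as_array() for b in boxes])


def total_distill_loss(det_loss, ld_per_anchor, assign: RegionAssignment,
                       cfg: DistillConfig):
    """L_total = L_det + lambda_main * sum_{main} L_LD + lambda_vlr * sum_{VLR} L_LD.

    `ld_per_anchor` indexes per-anchor LD losses (array, list, or dict keyed
    by anchor index); empty regions contribute zero.  Works on floats or on
    autodiff tensors (the trainer passes tensors).
    """
    def region_sum(indices):
        total = 0.0
        for k in indices:
            total = total + ld_per_anchor[int(k)]
        return total

    total = det_loss
    if cfg.lambda_main and len(assign.omega_main):
        total = total + cfg.lambda_main * region_sum(assign.omega_main)
    if cfg.lambda_vlr and len(assign.omega_vlr):
        total = total + cfg.lambda_vlr * region_sum(assign.omega_vlr)
    return total


# -- autodiff variants used by the trainer ---------------------------------

def tempered_kl_tensor(teacher_logits: np.ndarray, student_logits: Tensor,
                       tau: float, axis: int = -1) -> Tensor:
    """KL(p_T || p_S) at temperature tau, differentiable in the student.

    Returns elementwise KL summed over `axis` only (leading axes preserved),
    so callers can keep per-anchor structure.
    """
    t = np.asarray(teacher_logits, dtype=np.float64) / tau
    t = t - t.max(axis=axis, keepdims=True)
    log_pt = t - np.log(np.exp(t).sum(axis=axis, keepdims=True))
    pt = np.exp(log_pt)
    log_ps = log_softmax(student_logits * (1.0 / tau), axis=axis)
    ce = -(Tensor(pt) * log_ps).sum(axis=axis)
    # KL = CE minus the (student-independent) teacher entropy
    return ce + Tensor((pt * log_pt).sum(axis=axis))


def ld_loss_tensor(student_edge_logits: Tensor, teacher_edge_logits: np.ndarray,
                   cfg: DistillConfig) -> Tensor:
    """Per-anchor LD loss on (K, 4, B) logits; returns a (K,) tensor of
    edge-summed tempered KLs (x tau^2 if configured)."""
    kl = tempered_kl_tensor(teacher_edge_logits, student_edge_logits,
                            cfg.temperature, axis=-1)  # (K, 4)
    per_anchor = kl.sum(axis=-1)
    if cfg.tau_square_rescale:
        per_anchor = per_anchor * (cfg.temperature ** 2)
    return per_anchor
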