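"""Two-phase training protocol and evaluation.

Phase 1 (localization distillation): a wide teacher detector is fitted to the
box annotations, then frozen; the narrow student detector is optimized under
the composite objective (detection loss plus region-weighted distillation of
its tempered box-edge distributions toward the teacher's).  The student's
backbone-neck is then frozen as a stable feature extractor.

Phase 2 (segmentation fine-tuning): the frozen image encoder (with trainable
adapters), the frozen student pyramid, the prompt encoder, and the mask
decoder are wired into a promptable segmenter; gradients flow only to the
prompt encoder, the adapters, the decoder, and the dense gate alpha.  The
objective is Dice loss plus binary cross-entropy under a cosine-annealed
learning rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .distill import (DistillConfig, RegionAssignment, ld_loss_tensor,
                      select_regions, tempered_kl_tensor, total_distill_loss)
from .geometry import diou_matrix
from .metrics import accuracy, assd, bootstrap_ci, dice, hausdorff, iou_score
from .models import (Detector, ImageEncoder, MaskDecoder, ModelSpec,
                     decode_boxes_numpy, detection_loss, predict_boxes)
from .nn import AdamW, Module, Tensor, concat, cosine_lr
from .prompt_encoder import (BoxTokenizer, FeaturePyramid, PromptBundle,
                             PromptEncoder, inject_dense)
from .synthetic import SegSample

__all__ = [
    "RunConfig", "EvalReport", "Segmenter", "seg_loss",
    "pretrain_foundation", "train_teacher", "phase1_distill",
    "build_segmenter", "phase2_segment", "evaluate",
]

PROMPT_MODES = ("box", "dense", "sparse", "dense+sparse", "none")
DISTILL_MODES = ("none", "kd", "ld_main", "ld_main_vlr")


@dataclass
class RunConfig:
    """Training-run settings for both phases.

    phase2_lr defaults to 1e-4 with cosine annealing, matching the reference
    protocol; the miniature ablation preset overrides it (see docs/methods.md).
    """

    pretrain_epochs: int = 120
    pretrain_lr: float = 3e-3
    teacher_epochs: int = 12
    phase1_epochs: int = 10
    phase1_lr: float = 3e-3
    phase2_epochs: int = 40
    phase2_lr: float = 1e-4
    cosine: bool = True
    batch_size: int = 16
    prompt_mode: str = "dense+sparse"
    distill_mode: str = "ld_main_vlr"
    seeds: tuple = (10, 42, 123)

    def __post_init__(self):
        if self.prompt_mode not in PROMPT_MODES:
            raise ValueError(f"prompt_mode must be one of {PROMPT_MODES}")
        if self.distill_mode not in DISTILL_MODES:
            raise ValueError(f"distill_mode must be one of {DISTILL_MODES}")
        if self.phase1_epochs < 1 or self.phase2_epochs < 1:
            raise ValueError("epochs must be >= 1")


def seg_loss(logits: Tensor, masks: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Soft-Dice loss plus mean binary cross-entropy on logits."""
    masks = np.asarray(masks, dtype=np.float64)
    if tuple(logits.shape) != masks.shape:
        raise ValueError(f"shape mismatch: {logits.shape} vs {masks.shape}")
    y = Tensor(masks)
    p = logits.sigmoid()
    axes = tuple(range(1, masks.ndim))
    inter = (p * y).sum(axis=axes)
    denom = p.sum(axis=axes) + y.sum(axis=axes)
    dice_term = (1.0 - (2.0 * inter + eps) / (denom + eps)).mean()
    # numerically stable BCE: max(x,0) - x*y + log(1 + exp(-|x|))
    bce = (logits.maximum(0.0) - logits * y
           + ((-logits.abs()).exp() + 1.0).log()).mean()
    return dice_term + bce


# ---------------------------------------------------------------------------
# phase 1: detection and localization distillation
# ---------------------------------------------------------------------------

def _training_assignment(decoded: np.ndarray, gt_boxes, cfg: DistillConfig
                         ) -> RegionAssignment:
    """Threshold assignment plus the best-anchor guarantee: the highest-DIoU
    anchor for each ground-truth box is forced positive so training can
    bootstrap from uninformative initial predictions."""
    assign = select_regions(decoded, gt_boxes, cfg)
    if len(gt_boxes) == 0:
        return assign
    gt_arr = np.stack([b.as_array() for b in gt_boxes])
    mat = diou_matrix(decoded, gt_arr)  # (K, G)
    forced = np.unique(mat.argmax(axis=0))
    main = np.union1d(assign.omega_main, forced)
    vlr = np.setdiff1d(assign.omega_vlr, forced)
    matched = assign.matched_gt.copy()
    for g, k in enumerate(mat.argmax(axis=0)):
        if k not in assign.omega_main:
            matched[k] = g
    return RegionAssignment(scores=assign.scores, omega_main=main,
                            omega_vlr=vlr, matched_gt=matched)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _image_stack(samples) -> np.ndarray:
    return np.stack([s.image for s in samples])


def _detector_step_loss(det_out, batch_samples, distill_cfg, mode,
                        teacher_cache) -> Tensor:
    """Per-image composite objective, averaged over the batch."""
    total = None
    for i, sample in enumerate(batch_samples):
        edge_np = det_out.edge_logits.data[i]
        decoded = decode_boxes_numpy(edge_np, det_out.anchors, det_out.strides)
        assign = _training_assignment(decoded, sample.boxes, distill_cfg)
        loss_i = detection_loss(det_out, sample.boxes, assign, index=i)
        if mode != "none" and teacher_cache is not None:
            t_cls, t_edge = teacher_cache[sample.sample_id]
            if mode in ("ld_main", "ld_main_vlr"):
                ld_all = ld_loss_tensor(det_out.edge_logits[i], t_edge, distill_cfg)
                cfg_eff = distill_cfg if mode == "ld_main_vlr" else \
                    replace(distill_cfg, lambda_vlr=0.0)
                loss_i = total_distill_loss(loss_i, ld_all, assign, cfg_eff)
            elif mode == "kd":
                kd_all = tempered_kl_tensor(t_cls, det_out.class_logits[i],
                                            distill_cfg.temperature, axis=-1)
                if distill_cfg.tau_square_rescale:
                    kd_all = kd_all * (distill_cfg.temperature ** 2)
                loss_i = total_distill_loss(
                    loss_i, kd_all, assign, replace(distill_cfg, lambda_vlr=0.0))
        total = loss_i if total is None else total + loss_i
    return total * (1.0 / len(batch_samples))


def _fit_detector(det: Detector, samples, epochs: int, lr: float,
                  batch_size: int, rng: np.random.Generator,
                  distill_cfg: DistillConfig, mode: str = "none",
                  teacher_cache=None, cosine: bool = True) -> None:
    opt = AdamW(det.trainable_parameters(), lr=lr)
    n = len(samples)
    for epoch in range(epochs):
        if cosine:
            opt.lr = cosine_lr(lr, epoch, epochs)
        for idx in _batches(n, batch_size, rng):
            batch = [samples[i] for i in idx]
            out = det(Tensor(_image_stack(batch)))
            loss = _detector_step_loss(out, batch, distill_cfg, mode,
                                       teacher_cache)
            opt.zero_grad()
            loss.backward()
            opt.step()


def train_teacher(spec: ModelSpec, samples, cfg: RunConfig,
                  distill_cfg: DistillConfig, rng: np.random.Generator
                  ) -> Detector:
    """Plain detection fit of the wide teacher; returns it frozen."""
    teacher = Detector(spec.teacher_width, spec, rng)
    _fit_detector(teacher, samples, cfg.teacher_epochs, cfg.phase1_lr,
                  cfg.batch_size, rng, distill_cfg, mode="none")
    teacher.freeze()
    return teacher


def _cache_teacher_outputs(teacher: Detector, samples, batch_size: int) -> dict:
    cache = {}
    for start in range(0, len(samples), batch_size):
        batch = samples[start:start + batch_size]
        out = teacher(Tensor(_image_stack(batch)))
        for i, s in enumerate(batch):
            cache[s.sample_id] = (out.class_logits.data[i].copy(),
                                  out.edge_logits.data[i].copy())
    return cache


def phase1_distill(student: Detector, teacher: Detector, samples,
                   cfg: RunConfig, distill_cfg: DistillConfig,
                   rng: np.random.Generator) -> Detector:
    """Optimize the student under the composite distillation objective with
    the teacher fixed; freeze the student backbone-neck afterwards."""
    if cfg.distill_mode not in DISTILL_MODES:
        raise ValueError(f"unknown distill mode {cfg.distill_mode!r}")
    teacher.freeze()
    cache = None
    if cfg.distill_mode != "none":
        cache = _cache_teacher_outputs(teacher, samples, cfg.batch_size)
    _fit_detector(student, samples, cfg.phase1_epochs, cfg.phase1_lr,
                  cfg.batch_size, rng, distill_cfg, mode=cfg.distill_mode,
                  teacher_cache=cache)
    student.freeze()
    return student


# ---------------------------------------------------------------------------
# encoder pretraining (the stand-in for a pretrained foundation encoder)
# ---------------------------------------------------------------------------

def pretrain_foundation(spec: ModelSpec, samples, cfg: RunConfig,
                        rng: np.random.Generator) -> dict:
    """Self-supervised reconstruction pretraining of encoder and decoder.

    The stand-in for the pretrained promptable-segmentation backbone: the
    encoder compresses each image to its stride-16 embedding and the mask
    decoder (run without prompts) maps it back to an image-resolution field,
    trained to reconstruct the input under MSE.  Only images are consumed
    (no masks or boxes), so annotation budgets are untouched.  Returns
    {"encoder": backbone state, "decoder": state} for phase 2, where the
    encoder is frozen and the decoder is fine-tuned.
    """
    enc = ImageEncoder(spec, rng, frozen=False, use_adapters=False)
    dec = MaskDecoder(spec, rng)
    opt = AdamW(enc.trainable_parameters() + dec.trainable_parameters(),
                lr=cfg.pretrain_lr)
    n = len(samples)
    for epoch in range(cfg.pretrain_epochs):
        if cfg.cosine:
            opt.lr = cosine_lr(cfg.pretrain_lr, epoch, cfg.pretrain_epochs)
        for idx in _batches(n, cfg.batch_size, rng):
            batch = [samples[i] for i in idx]
            images = _image_stack(batch)
            recon = dec(enc(Tensor(images)), None)
            err = recon - Tensor(images)
            loss = (err * err).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
    return {"encoder": enc.backbone_state(), "decoder": dec.state_dict()}


# ---------------------------------------------------------------------------
# phase 2: promptable segmentation
# ---------------------------------------------------------------------------

class Segmenter(Module):
    """Frozen encoder + adapters, optional frozen student pyramid, prompt
    encoder, and mask decoder, wired per prompt mode."""

    def __init__(self, spec: ModelSpec, prompt_mode: str,
                 rng: np.random.Generator, student: Detector | None = None,
                 pretrained: dict | None = None):
        if prompt_mode not in PROMPT_MODES:
            raise ValueError(f"prompt_mode must be one of {PROMPT_MODES}")
        needs_student = prompt_mode in ("dense", "sparse", "dense+sparse")
        if needs_student and student is None:
            raise ValueError(
                f"prompt mode {prompt_mode!r} requires a phase-1 student "
                "(run the distillation phase first)")
        self.spec = spec
        self.prompt_mode = prompt_mode
        self.encoder = ImageEncoder(spec, rng, frozen=True, use_adapters=True)
        self.student = student
        if student is not None:
            student.freeze()
        if needs_student:
            self.prompt_encoder = PromptEncoder(
                spec.pyramid_channels(spec.student_width), spec.fused_channels,
                spec.embed_dim, spec.num_sparse_tokens, rng,
                use_dense="dense" in prompt_mode,
                use_sparse="sparse" in prompt_mode)
        if prompt_mode == "box":
            self.box_tokenizer = BoxTokenizer(spec.embed_dim, spec.image_size, rng)
        self.decoder = MaskDecoder(spec, rng)
        if pretrained is not None:
            self.encoder.load_backbone(pretrained["encoder"])
            self.decoder.load_state_dict(pretrained["decoder"])
        self._pyramid_cache: dict[str, tuple] = {}
        self._pred_box_cache: dict[str, list] = {}

    # -- feature plumbing --------------------------------------------------
    def _pyramid_for(self, batch) -> FeaturePyramid:
        missing = [s for s in batch if s.sample_id not in self._pyramid_cache]
        if missing:
            p3, p4, p5 = self.student.pyramid(Tensor(_image_stack(missing)))
            for i, s in enumerate(missing):
                self._pyramid_cache[s.sample_id] = (
                    p3.data[i].copy(), p4.data[i].copy(), p5.data[i].copy())
        stacks = [np.stack([self._pyramid_cache[s.sample_id][lvl] for s in batch])
                  for lvl in range(3)]
        return FeaturePyramid(*(Tensor(a) for a in stacks))

    def _boxes_for(self, batch, predicted: bool) -> dict[str, list]:
        """Box prompts per sample: mask-derived ground truth during training,
        the student's predicted boxes at inference when a student is present
        (the automatic-pipeline setting, where box localization noise
        propagates into the decoder)."""
        if not predicted or self.student is None:
            return {s.sample_id: s.boxes for s in batch}
        missing = [s for s in batch if s.sample_id not in self._pred_box_cache]
        if missing:
            pred = predict_boxes(self.student, _image_stack(missing),
                                 max_boxes=3)
            for s, boxes in zip(missing, pred):
                self._pred_box_cache[s.sample_id] = boxes
        return {s.sample_id: self._pred_box_cache[s.sample_id] for s in batch}

    def _bundle_for(self, batch, boxes_by_id: dict | None = None
                    ) -> PromptBundle | None:
        if self.prompt_mode == "none":
            return None
        if self.prompt_mode == "box":
            if boxes_by_id is None:
                boxes_by_id = {s.sample_id: s.boxes for s in batch}
            per_sample = [self.box_tokenizer(boxes_by_id[s.sample_id])
                          for s in batch]
            counts = {t.shape[0] for t in per_sample}
            if len(counts) != 1:
                raise ValueError("box-token batches must share the box count")
            (t_count,) = counts
            tokens = concat([t.reshape(1, t_count, self.spec.embed_dim)
                             for t in per_sample], axis=0)
            return PromptBundle(dense=None, alpha=None, sparse=None,
                                box_tokens=tokens)
        return self.prompt_encoder(self._pyramid_for(batch))

    def forward(self, batch: list[SegSample],
                boxes_by_id: dict | None = None) -> Tensor:
        images = Tensor(_image_stack(batch))
        z_img = self.encoder(images)
        bundle = self._bundle_for(batch, boxes_by_id)
        if bundle is not None and bundle.dense is not None:
            z_cond = inject_dense(z_img, bundle.dense, bundle.alpha)
        else:
            z_cond = z_img
        return self.decoder(z_cond, bundle)

    def _grouped(self, batch, boxes_by_id: dict | None = None):
        """Split a batch into sub-batches with a common box count (the box
        tokenizer emits two tokens per instance, so counts must agree)."""
        if self.prompt_mode != "box":
            return [batch]
        if boxes_by_id is None:
            boxes_by_id = {s.sample_id: s.boxes for s in batch}
        groups: dict[int, list] = {}
        for s in batch:
            groups.setdefault(len(boxes_by_id[s.sample_id]), []).append(s)
        return [groups[k] for k in sorted(groups)]

    def predict_logits(self, samples, batch_size: int = 16) -> list[np.ndarray]:
        by_id = {}
        for start in range(0, len(samples), batch_size):
            chunk = samples[start:start + batch_size]
            boxes_by_id = self._boxes_for(chunk, predicted=True) \
                if self.prompt_mode == "box" else None
            for group in self._grouped(chunk, boxes_by_id):
                logits = self.forward(group, boxes_by_id)
                for i, s in enumerate(group):
                    by_id[s.sample_id] = logits.data[i]
        return [by_id[s.sample_id] for s in samples]

    def predict_masks(self, samples, batch_size: int = 16) -> list[np.ndarray]:
        """Binary masks at the 0-logit (probability 0.5) threshold."""
        return [lg > 0 for lg in self.predict_logits(samples, batch_size)]


def build_segmenter(spec: ModelSpec, prompt_mode: str,
                    rng: np.random.Generator,
                    student: Detector | None = None) -> Segmenter:
    return Segmenter(spec, prompt_mode, rng, student)


def phase2_segment(segmenter: Segmenter, samples, cfg: RunConfig,
                   rng: np.random.Generator) -> Segmenter:
    """Fit the trainable set {prompt encoder, adapters, decoder, alpha} on
    mask supervision with Dice+BCE and a cosine-annealed learning rate."""
    trainable = segmenter.trainable_parameters()
    opt = AdamW(trainable, lr=cfg.phase2_lr)
    n = len(samples)
    for epoch in range(cfg.phase2_epochs):
        if cfg.cosine:
            opt.lr = cosine_lr(cfg.phase2_lr, epoch, cfg.phase2_epochs)
        for idx in _batches(n, cfg.batch_size, rng):
            batch = [samples[i] for i in idx]
            for group in segmenter._grouped(batch):
                logits = segmenter(group)
                masks = np.stack([s.union_mask for s in group])
                loss = seg_loss(logits, masks) * (len(group) / len(batch))
                opt.zero_grad()
                loss.backward()
                opt.step()
    return segmenter


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-case metrics, their means, and a bootstrap CI on mean Dice."""

    case_ids: list[str]
    per_case: dict[str, list[float]]
    means: dict[str, float]
    ci_dice: tuple[float, float]
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {"case_ids": self.case_ids, "per_case": self.per_case,
                   "means": self.means, "ci_dice": list(self.ci_dice),
                   "metadata": self.metadata}
        return json.dumps(payload, indent=2, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "EvalReport":
        d = json.loads(text)
        return EvalReport(case_ids=d["case_ids"], per_case=d["per_case"],
                          means=d["means"], ci_dice=tuple(d["ci_dice"]),
                          metadata=d.get("metadata", {}))


def evaluate(segmenter: Segmenter, samples, n_boot: int = 1000,
             seed: int = 0, metadata: dict | None = None) -> EvalReport:
    preds = segmenter.predict_masks(samples)
    per_case = {m: [] for m in ("dice", "iou", "acc", "hd", "assd")}
    for s, pred in zip(samples, preds):
        gt = s.union_mask
        per_case["dice"].append(dice(pred, gt))
        per_case["iou"].append(iou_score(pred, gt))
        per_case["acc"].append(accuracy(pred, gt))
        per_case["hd"].append(hausdorff(pred, gt))
        per_case["assd"].append(assd(pred, gt))
    means = {k: float(np.mean(v)) for k, v in per_case.items()}
    ci = bootstrap_ci(per_case["dice"], n_boot=n_boot, seed=seed)
    return EvalReport(case_ids=[s.sample_id for s in samples],
                      per_case=per_case, means=means, ci_dice=ci,
                      metadata=metadata or {})
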