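"""Miniature trainable stand-ins: frozen image encoder with adapters, student
and teacher detector pyramids, detection head with edge-distribution
regression, and a two-way-attention mask decoder.

These are small convolutional networks sized for CPU-minute training on
synthetic shape images; the object under test is the prompting/distillation
mechanism, not backbone scale.  The teacher pyramid uses 4x the student's
channel widths, giving a parameter count well over 4x the student's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AnchorPoint
from .nn import (Conv2d, LayerNorm, Linear, Module, MultiheadAttention,
                 Parameter, Tensor, concat, pixel_shuffle2, softmax)
from .prompt_encoder import PromptBundle, sinusoidal_position_encoding

__all__ = [
    "ModelSpec", "DetectionOutput", "ImageEncoder", "PyramidNet", "Detector",
    "DetectionHead", "MaskDecoder", "build_anchors", "decode_boxes_tensor",
    "diou_tensor", "decode_boxes_numpy", "detection_loss", "soft_bin_targets",
]


@dataclass
class ModelSpec:
    """Widths and depths of every miniature component."""

    image_size: int = 64
    embed_dim: int = 64                      # D, image-embedding channels
    encoder_widths: tuple = (16, 32, 48, 64)  # four stride-2 blocks -> stride 16
    adapter_width: int = 8
    student_width: int = 8                   # P3 channels; P4/P5 are 2x/4x
    teacher_width: int = 32
    fused_channels: int = 64                 # C of the fused stride-8 map
    num_sparse_tokens: int = 4               # K
    bins: int = 8                            # B, edge-distribution bins
    decoder_rounds: int = 2                  # L
    decoder_heads: int = 2

    def __post_init__(self):
        if self.teacher_width < 4 * self.student_width:
            raise ValueError("teacher width must be at least 4x student width")
        if self.encoder_widths[-1] != self.embed_dim:
            raise ValueError("last encoder width must equal embed_dim")
        if any(w <= 0 for w in (*self.encoder_widths, self.adapter_width,
                                self.student_width, self.teacher_width,
                                self.fused_channels, self.bins)):
            raise ValueError("all widths must be positive")

    def pyramid_channels(self, width: int) -> tuple[int, int, int]:
        return (width, 2 * width, 4 * width)


@dataclass
class DetectionOutput:
    """Per-anchor predictions, flattened across pyramid levels (P3 row-major,
    then P4, then P5)."""

    anchors: list                    # K AnchorPoint
    class_logits: Tensor             # (N, K, 2) background/foreground
    edge_logits: Tensor              # (N, K, 4, B) in edge order (t, b, l, r)
    strides: np.ndarray = field(repr=False, default=None)  # (K,)

    @property
    def num_anchors(self) -> int:
        return len(self.anchors)

    @property
    def objectness(self) -> Tensor:
        """Foreground-vs-background logit (difference of class logits)."""
        return self.class_logits[:, :, 1] - self.class_logits[:, :, 0]


class AdapterBlock(Module):
    """Residual bottleneck: 1x1 down-project -> ReLU -> 1x1 up-project.

    The up-projection is zero-initialized so a fresh adapter is the identity.
    """

    def __init__(self, channels: int, bottleneck: int, rng: np.random.Generator):
        self.down = Conv2d(channels, bottleneck, 1, rng)
        self.up = Conv2d(bottleneck, channels, 1, rng, zero_init=True)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.up(self.down(x).relu())


class ImageEncoder(Module):
    """Four stride-2 conv blocks -> stride-16, D-channel embedding.

    When `frozen`, the backbone convolutions receive no parameter updates
    while the interleaved adapter bottlenecks remain trainable.
    """

    def __init__(self, spec: ModelSpec, rng: np.random.Generator,
                 frozen: bool = True, use_adapters: bool = True):
        widths = spec.encoder_widths
        in_ch = 1
        self.blocks = []
        self.adapters = []
        for w in widths:
            self.blocks.append(Conv2d(in_ch, w, 3, rng, stride=2, padding=1))
            if use_adapters:
                self.adapters.append(AdapterBlock(w, spec.adapter_width, rng))
            in_ch = w
        self.use_adapters = use_adapters
        self.frozen = frozen
        if frozen:
            for blk in self.blocks:
                blk.freeze()

    def backbone_parameters(self):
        return [p for blk in self.blocks for p in blk.parameters()]

    def adapter_parameters(self):
        return [p for ad in self.adapters for p in ad.parameters()]

    def backbone_state(self) -> dict:
        return {f"block{i}.{k}": v for i, blk in enumerate(self.blocks)
                for k, v in blk.state_dict().items()}

    def load_backbone(self, state: dict) -> None:
        for i, blk in enumerate(self.blocks):
            blk.load_state_dict({k.split(".", 1)[1]: v for k, v in state.items()
                                 if k.startswith(f"block{i}.")})

    def forward(self, images: Tensor) -> Tensor:
        if images.ndim == 3:
            images = images.reshape(images.shape[0], 1, *images.shape[1:])
        if images.shape[2] % 16 or images.shape[3] % 16:
            raise ValueError("image resolution must be divisible by 16")
        x = images
        for i, blk in enumerate(self.blocks):
            x = blk(x).relu()
            if self.use_adapters:
                x = self.adapters[i](x)
        return x  # (N, D, H/16, W/16)


class PyramidNet(Module):
    """Tiny CNN backbone-neck producing P3/P4/P5 at strides 8/16/32 with
    channels (w, 2w, 4w)."""

    def __init__(self, width: int, rng: np.random.Generator):
        self.width = width
        self.stem = Conv2d(1, width, 3, rng, stride=2, padding=1)
        self.down4 = Conv2d(width, width, 3, rng, stride=2, padding=1)
        self.down8 = Conv2d(width, width, 3, rng, stride=2, padding=1)
        self.down16 = Conv2d(width, 2 * width, 3, rng, stride=2, padding=1)
        self.down32 = Conv2d(2 * width, 4 * width, 3, rng, stride=2, padding=1)

    def forward(self, images: Tensor):
        if images.ndim == 3:
            images = images.reshape(images.shape[0], 1, *images.shape[1:])
        if images.shape[2] % 32 or images.shape[3] % 32:
            raise ValueError("image resolution must be divisible by 32")
        x = self.stem(images).relu()
        x = self.down4(x).relu()
        p3 = self.down8(x).relu()
        p4 = self.down16(p3).relu()
        p5 = self.down32(p4).relu()
        return p3, p4, p5


def build_anchors(image_size: int) -> tuple[list, np.ndarray]:
    """Anchor points at every pyramid-cell center, P3 row-major then P4, P5."""
    anchors, strides = [], []
    for stride in (8, 16, 32):
        n = image_size // stride
        for i in range(n):
            for j in range(n):
                anchors.append(AnchorPoint((j + 0.5) * stride, (i + 0.5) * stride, stride))
                strides.append(stride)
    return anchors, np.asarray(strides, dtype=np.float64)


class DetectionHead(Module):
    """YOLO-flavored per-cell head: 2-way class logits plus 4xB edge logits."""

    def __init__(self, pyramid_channels: tuple[int, int, int], bins: int,
                 image_size: int, rng: np.random.Generator):
        self.bins = bins
        self.image_size = image_size
        self.stems = [Conv2d(c, c, 3, rng, padding=1) for c in pyramid_channels]
        self.cls_heads = [Conv2d(c, 2, 1, rng) for c in pyramid_channels]
        self.edge_heads = [Conv2d(c, 4 * bins, 1, rng) for c in pyramid_channels]
        self._anchors, self._strides = build_anchors(image_size)

    def forward(self, pyramid) -> DetectionOutput:
        cls_parts, edge_parts = [], []
        n = pyramid[0].shape[0]
        for level, (feat, stem, ch, eh) in enumerate(
                zip(pyramid, self.stems, self.cls_heads, self.edge_heads)):
            x = stem(feat).relu()
            cls = ch(x)    # (N, 2, h, w)
            edge = eh(x)   # (N, 4B, h, w)
            h, w = cls.shape[2], cls.shape[3]
            cls_parts.append(cls.transpose(0, 2, 3, 1).reshape(n, h * w, 2))
            edge_parts.append(edge.transpose(0, 2, 3, 1).reshape(n, h * w, 4, self.bins))
        return DetectionOutput(
            anchors=self._anchors,
            class_logits=concat(cls_parts, axis=1),
            edge_logits=concat(edge_parts, axis=1),
            strides=self._strides,
        )


class Detector(Module):
    """Pyramid backbone plus detection head."""

    def __init__(self, width: int, spec: ModelSpec, rng: np.random.Generator):
        self.pyramid = PyramidNet(width, rng)
        self.head = DetectionHead(spec.pyramid_channels(width), spec.bins,
                                  spec.image_size, rng)

    def forward(self, images: Tensor) -> DetectionOutput:
        return self.head(self.pyramid(images))


def decode_boxes_tensor(edge_logits: Tensor, anchors: list,
                        strides: np.ndarray) -> Tensor:
    """Differentiable expectation decode of (N, K, 4, B) edge logits into
    (N, K, 4) boxes (xmin, ymin, xmax, ymax); edge order is (t, b, l, r) and
    the per-anchor bin width is the anchor stride."""
    bins = edge_logits.shape[-1]
    idx = Tensor(np.arange(bins, dtype=np.float64))
    p = softmax(edge_logits, axis=-1)
    dist = (p * idx).sum(axis=-1) * Tensor(strides[None, :, None])  # (N, K, 4)
    centers = np.array([[a.cx, a.cy] for a in anchors])  # (K, 2)
    cx = Tensor(centers[None, :, 0])
    cy = Tensor(centers[None, :, 1])
    dt, db = dist[:, :, 0], dist[:, :, 1]
    dl, dr = dist[:, :, 2], dist[:, :, 3]
    n, k = dt.shape
    parts = [(cx - dl), (cy - dt), (cx + dr), (cy + db)]
    return concat([t.reshape(n, k, 1) for t in parts], axis=2)


def diou_tensor(pred: Tensor, gt: np.ndarray) -> Tensor:
    """Differentiable DIoU between (M, 4) predicted boxes and matched (M, 4)
    ground-truth boxes."""
    g = Tensor(np.asarray(gt, dtype=np.float64))
    zero = Tensor(np.zeros(pred.shape[0]))
    iw = (pred[:, 2].minimum(g[:, 2]) - pred[:, 0].maximum(g[:, 0])).maximum(zero)
    ih = (pred[:, 3].minimum(g[:, 3]) - pred[:, 1].maximum(g[:, 1])).maximum(zero)
    inter = iw * ih
    area_p = (pred[:, 2] - pred[:, 0]) * (pred[:, 3] - pred[:, 1])
    area_g = (g[:, 2] - g[:, 0]) * (g[:, 3] - g[:, 1])
    union = area_p + area_g - inter + 1e-9
    iou_v = inter / union
    dx = 0.5 * (pred[:, 0] + pred[:, 2]) - 0.5 * (g[:, 0] + g[:, 2])
    dy = 0.5 * (pred[:, 1] + pred[:, 3]) - 0.5 * (g[:, 1] + g[:, 3])
    d2 = dx * dx + dy * dy
    cw = pred[:, 2].maximum(g[:, 2]) - pred[:, 0].minimum(g[:, 0])
    ch = pred[:, 3].maximum(g[:, 3]) - pred[:, 1].minimum(g[:, 1])
    c2 = cw * cw + ch * ch + 1e-9
    return iou_v - d2 / c2


class MaskDecoder(Module):
    """Two-way attention between prompt tokens and image embedding, then
    mask logits from the output token.

    Token set = [output token] (+) sparse tokens (+) optional box tokens.
    Each of the L rounds runs token self-attention, token-to-image cross
    attention, and image-to-token cross attention (all with residual +
    LayerNorm).  The embedding is then upscaled to input resolution by four
    stride-2 transposed convolutions (realized as 1x1 conv + pixel shuffle,
    channels halving per stage), and the mask logits are the dot product of
    the projected output token with the upsampled embedding at every pixel.
    """

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        d = spec.embed_dim
        self.spec = spec
        self.output_token = Parameter(rng.normal(0, 0.02, size=(1, d)))
        self.rounds = []
        for _ in range(spec.decoder_rounds):
            self.rounds.append({
                "self": MultiheadAttention(d, spec.decoder_heads, rng),
                "self_ln": LayerNorm(d),
                "t2i": MultiheadAttention(d, spec.decoder_heads, rng),
                "t2i_ln": LayerNorm(d),
                "i2t": MultiheadAttention(d, spec.decoder_heads, rng,
                                          zero_out=True),
            })
        # expose round submodules for parameter discovery
        for i, r in enumerate(self.rounds):
            for key, mod in r.items():
                setattr(self, f"round{i}_{key}", mod)
        chans = [d, d // 2, d // 4, d // 8, d // 16]
        self.ups = [Conv2d(chans[i], 4 * chans[i + 1], 1, rng)
                    for i in range(4)]
        # the attention-refined part of the output token enters the readout
        # through a zero-initialized gate: at initialization the readout
        # weights are the shared learned token, and per-image refinements
        # grow only as training demands them
        self.token_gate = Linear(d, d, rng, zero_init=True)
        self.token_proj = Linear(d, chans[-1], rng)
        # scalar output bias: global operating-point calibration of the mask
        # logits without disturbing the spatial readout weights
        self.mask_bias = Parameter(np.zeros(()))

    def _image_pe(self, h: int, w: int) -> np.ndarray:
        ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        coords = np.stack([(xs.ravel() + 0.5) / w, (ys.ravel() + 0.5) / h], axis=1)
        return sinusoidal_position_encoding(coords, self.spec.embed_dim)

    def _assemble_tokens(self, n: int, bundle: PromptBundle | None) -> Tensor:
        d = self.spec.embed_dim
        out_tok = self.output_token.reshape(1, 1, d)
        ones = Tensor(np.ones((n, 1, 1)))
        parts = [out_tok * ones]  # broadcast output token over the batch
        if bundle is not None and bundle.sparse is not None:
            if bundle.sparse.shape[-1] != d:
                raise ValueError("sparse token dim must equal embed_dim")
            parts.append(bundle.sparse)
        if bundle is not None and bundle.box_tokens is not None:
            if bundle.box_tokens.shape[-1] != d:
                raise ValueError("box token dim must equal embed_dim")
            parts.append(bundle.box_tokens)
        return concat(parts, axis=1) if len(parts) > 1 else parts[0]

    def forward(self, z_cond: Tensor, bundle: PromptBundle | None = None) -> Tensor:
        n, d, h, w = z_cond.shape
        if d != self.spec.embed_dim:
            raise ValueError("embedding dim mismatch")
        tokens = self._assemble_tokens(n, bundle)
        img = z_cond.reshape(n, d, h * w).transpose(0, 2, 1)  # (N, S, D)
        pe = Tensor(self._image_pe(h, w)[None, :, :])
        for r in self.rounds:
            tokens = r["self_ln"](tokens + r["self"](tokens, tokens))
            tokens = r["t2i_ln"](tokens + r["t2i"](tokens, img, kv_pe=pe))
            # no LayerNorm on the image stream: at miniature width the
            # content is nearly rank-one and per-position normalization
            # would erase its scale (the signal the mask readout needs)
            img = img + r["i2t"](img, tokens, q_pe=pe)
        out_tok = self.output_token + self.token_gate(tokens[:, 0, :])  # (N, D)
        feat = img.transpose(0, 2, 1).reshape(n, d, h, w)
        for i, up in enumerate(self.ups):
            feat = pixel_shuffle2(up(feat))
            if i < len(self.ups) - 1:
                feat = feat.relu()                     # (N, D/16, 16h, 16w)
        tok = self.token_proj(out_tok)                 # (N, D/16)
        logits = (feat * tok.reshape(n, -1, 1, 1)).sum(axis=1)
        return logits + self.mask_bias                 # (N, 16h, 16w)


def decode_boxes_numpy(edge_logits: np.ndarray, anchors: list,
                       strides: np.ndarray) -> np.ndarray:
    """Plain-numpy expectation decode of (K, 4, B) logits -> (K, 4) boxes;
    used where no gradient is needed (label assignment, teacher caching)."""
    z = np.asarray(edge_logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=-1, keepdims=True)
    dist = (p * np.arange(z.shape[-1])).sum(axis=-1) * strides[:, None]  # (K, 4)
    centers = np.array([[a.cx, a.cy] for a in anchors])
    dt, db, dl, dr = dist[:, 0], dist[:, 1], dist[:, 2], dist[:, 3]
    return np.stack([centers[:, 0] - dl, centers[:, 1] - dt,
                     centers[:, 0] + dr, centers[:, 1] + db], axis=1)


def soft_bin_targets(distances: np.ndarray, bins: int) -> np.ndarray:
    """Distribution-focal soft targets: distance d (in bin units) puts weight
    (ceil(d)-d, d-floor(d)) on its two flanking bins; clipped to the bin range."""
    d = np.clip(np.asarray(distances, dtype=np.float64), 0.0, bins - 1 - 1e-9)
    lo = np.floor(d).astype(int)
    hi = lo + 1
    w_hi = d - lo
    out = np.zeros(d.shape + (bins,))
    np.put_along_axis(out, lo[..., None], (1.0 - w_hi)[..., None], axis=-1)
    np.put_along_axis(out, hi[..., None], w_hi[..., None], axis=-1)
    return out


def detection_loss(out: DetectionOutput, gt_boxes, assign, index: int = 0) -> Tensor:
    """Miniature detection objective for one image of a batched output.

    Three terms: 2-way class cross-entropy on objectness (positives are the
    assigned main region; VLR anchors are excluded from this term), mean
    (1 - DIoU) between decoded boxes of main anchors and their matched ground
    truth, and soft-bin cross-entropy on the edge distributions of main
    anchors.  With an empty main region only the objectness term remains.
    """
    from .nn import log_softmax as _lsm  # local import to avoid cycle at module load

    cls = out.class_logits[index]      # (K, 2)
    edges = out.edge_logits[index]     # (K, 4, B)
    k = out.num_anchors
    main = np.asarray(assign.omega_main, dtype=int)
    vlr = np.asarray(assign.omega_vlr, dtype=int)

    targets = np.zeros(k, dtype=np.float64)
    targets[main] = 1.0
    consider = np.ones(k, dtype=np.float64)
    consider[vlr] = 0.0  # VLR anchors receive distillation only
    one_hot = np.stack([1.0 - targets, targets], axis=1)
    ce = -(Tensor(one_hot) * _lsm(cls, axis=-1)).sum(axis=-1)
    cls_loss = (ce * Tensor(consider)).sum() * (1.0 / max(consider.sum(), 1.0))
    if main.size == 0:
        return cls_loss

    sub_anchors = [out.anchors[i] for i in main]
    sub_strides = out.strides[main]
    sel_edges = edges[main]  # (M, 4, B)
    decoded = decode_boxes_tensor(
        sel_edges.reshape(1, main.size, 4, edges.shape[-1]),
        sub_anchors, sub_strides)[0]  # (M, 4)
    gt_arr = np.stack([gt_boxes[assign.matched_gt[i]].as_array() for i in main])
    box_loss = (1.0 - diou_tensor(decoded, gt_arr)).mean()

    centers = np.array([[a.cx, a.cy] for a in sub_anchors])
    dt = (centers[:, 1] - gt_arr[:, 1]) / sub_strides
    db = (gt_arr[:, 3] - centers[:, 1]) / sub_strides
    dl = (centers[:, 0] - gt_arr[:, 0]) / sub_strides
    dr = (gt_arr[:, 2] - centers[:, 0]) / sub_strides
    dists = np.stack([dt, db, dl, dr], axis=1)  # (M, 4)
    bins = edges.shape[-1]
    w = soft_bin_targets(dists, bins)
    bin_ce = -(Tensor(w) * _lsm(sel_edges, axis=-1)).sum(axis=-1)  # (M, 4)
    bin_loss = bin_ce.mean()
    return cls_loss + box_loss + bin_loss


def _greedy_nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float) -> list[int]:
    order = np.argsort(-scores)
    keep: list[int] = []
    for i in order:
        ok = True
        for j in keep:
            iw = min(boxes[i, 2], boxes[j, 2]) - max(boxes[i, 0], boxes[j, 0])
            ih = min(boxes[i, 3], boxes[j, 3]) - max(boxes[i, 1], boxes[j, 1])
            inter = max(iw, 0.0) * max(ih, 0.0)
            a = (boxes[i, 2] - boxes[i, 0]) * (boxes[i, 3] - boxes[i, 1])
            b = (boxes[j, 2] - boxes[j, 0]) * (boxes[j, 3] - boxes[j, 1])
            union = a + b - inter
            if union > 0 and inter / union > iou_thresh:
                ok = False
                break
        if ok:
            keep.append(int(i))
    return keep


def predict_boxes(detector: "Detector", images: np.ndarray,
                  max_boxes: int = 3, score_thresh: float = 0.3,
                  iou_thresh: float = 0.5, image_size: int | None = None):
    """Decode a detector's predictions into per-image box lists.

    Greedy NMS on objectness-scored decoded boxes; at least the single
    best-scoring box is always kept so the downstream prompt is never empty.
    """
    from .geometry import Box  # local to avoid import cycle in type checks

    out = detector(Tensor(np.asarray(images, dtype=np.float64)))
    size = image_size or detector.head.image_size
    results = []
    for i in range(images.shape[0]):
        decoded = decode_boxes_numpy(out.edge_logits.data[i], out.anchors,
                                     out.strides)
        z = out.class_logits.data[i]
        scores = 1.0 / (1.0 + np.exp(-(z[:, 1] - z[:, 0])))
        keep = _greedy_nms(decoded, scores, iou_thresh)
        chosen = [k for k in keep if scores[k] >= score_thresh][:max_boxes]
        if not chosen:
            chosen = keep[:1]
        boxes = []
        for k in chosen:
            x1, y1, x2, y2 = np.clip(decoded[k], 0, size)
            boxes.append(Box(min(x1, x2), min(y1, y2), max(x1, x2), max(y1, y2)))
        results.append(boxes)
    return results
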