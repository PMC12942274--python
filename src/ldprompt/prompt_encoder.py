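"""Dense/sparse feature-prompt encoder.

The detector's multi-scale pyramid (P3/P4/P5 at strides 8/16/32) is fused to a
single stride-8 map: P4 and P5 are bilinearly upsampled to P3's resolution,
channel-concatenated with P3, and mixed by a 1x1 (channel reduction) then 3x3
(spatial smoothing, reflect padded) convolution.  From the fused map two
complementary prompts are derived:

* dense prompt: a stride-2 convolutional head halves the resolution to stride
  16 (the image-embedding scale) and maps channels to the embedding dim D; it
  is injected residually, Z_cond = Z_img + alpha * P_dense, with the scalar
  gate alpha learned from an initial value of exactly 0 so conditioning is
  strictly additive at initialization.
* sparse prompt: global average pooling squeezes the fused map to a channel
  vector, a two-layer perceptron projects it to K*D, and the result is
  partitioned into K tokens (default K=4) that join the decoder's attention.

The box-prompt baseline encodes a box's two corners with sinusoidal positional
encodings plus a learned corner-type embedding each.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import Box
from .nn import (Conv2d, Linear, Module, Parameter, Tensor, bilinear_resize,
                 concat, global_avg_pool)

__all__ = [
    "FeaturePyramid", "FusedFeature", "PromptBundle", "ImageEmbedding",
    "PyramidFuser", "DenseHead", "SparseHead", "BoxTokenizer", "PromptEncoder",
    "inject_dense", "sinusoidal_position_encoding",
]


@dataclass
class FeaturePyramid:
    """P3/P4/P5 maps at strides 8/16/32, shape (N, C_l, H_l, W_l)."""

    p3: Tensor
    p4: Tensor
    p5: Tensor

    def __post_init__(self):
        for a, b in ((self.p3, self.p4), (self.p4, self.p5)):
            if a.shape[2] != 2 * b.shape[2] or a.shape[3] != 2 * b.shape[3]:
                raise ValueError("pyramid spatial dims must halve per level")
        if not (self.p3.shape[0] == self.p4.shape[0] == self.p5.shape[0]):
            raise ValueError("pyramid batch dims must agree")

    @property
    def levels(self):
        return (self.p3, self.p4, self.p5)


@dataclass
class FusedFeature:
    """Stride-8 fusion of the pyramid; spatial dims equal P3's."""

    fused: Tensor


@dataclass
class PromptBundle:
    """Everything that conditions the mask decoder for one batch."""

    dense: Tensor | None           # (N, D, H/16, W/16)
    alpha: Tensor | None           # scalar gate
    sparse: Tensor | None          # (N, K, D)
    box_tokens: Tensor | None      # (N, 2*n_boxes, D)


@dataclass
class ImageEmbedding:
    """Frozen-encoder output at stride 16 and its conditioned counterpart."""

    z_img: Tensor
    z_cond: Tensor | None = None


def sinusoidal_position_encoding(coords: np.ndarray, dim: int,
                                 max_period: float = 128.0) -> np.ndarray:
    """Sin/cos encoding of (n, 2) normalized coordinates into (n, dim).

    Half the channels encode x, half y, with geometrically spaced frequencies
    from 1 to max_period cycles over the unit interval.
    """
    if dim % 4 != 0:
        raise ValueError("encoding dim must be divisible by 4")
    coords = np.asarray(coords, dtype=np.float64)
    n_freq = dim // 4
    freqs = max_period ** (np.arange(n_freq) / max(n_freq - 1, 1))
    out = []
    for axis in range(2):
        ang = 2.0 * np.pi * coords[:, axis:axis + 1] * freqs[None, :]
        out.extend([np.sin(ang), np.cos(ang)])
    return np.concatenate(out, axis=1)


class PyramidFuser(Module):
    """1x1 channel reduction then 3x3 reflect-padded smoothing on the
    upsampled, concatenated pyramid."""

    def __init__(self, in_channels: tuple[int, int, int], fused_channels: int,
                 rng: np.random.Generator):
        total = sum(in_channels)
        self.reduce = Conv2d(total, fused_channels, 1, rng)
        self.smooth = Conv2d(fused_channels, fused_channels, 3, rng,
                             padding=1, pad_mode="reflect")

    def forward(self, pyr: FeaturePyramid) -> FusedFeature:
        h, w = pyr.p3.shape[2], pyr.p3.shape[3]
        up4 = bilinear_resize(pyr.p4, h, w)
        up5 = bilinear_resize(pyr.p5, h, w)
        stacked = concat([pyr.p3, up4, up5], axis=1)
        return FusedFeature(self.smooth(self.reduce(stacked)))


class DenseHead(Module):
    """Stride-2 convolutional head: stride-8 fused map -> stride-16 dense
    prompt with D channels.  Odd inputs are symmetrically (reflect) padded to
    even size first."""

    def __init__(self, fused_channels: int, embed_dim: int, rng: np.random.Generator):
        self.conv = Conv2d(fused_channels, embed_dim, 3, rng, stride=2,
                           padding=1, pad_mode="reflect")

    def forward(self, fused: FusedFeature) -> Tensor:
        x = fused.fused
        if x.shape[2] % 2 or x.shape[3] % 2:
            raise ValueError("fused map must have even spatial dims "
                             "(pad inputs to an even multiple of the stride)")
        return self.conv(x)


class SparseHead(Module):
    """GAP -> two-layer perceptron -> K tokens of dimension D."""

    def __init__(self, fused_channels: int, embed_dim: int, num_tokens: int,
                 rng: np.random.Generator):
        if num_tokens < 1:
            raise ValueError("need at least one sparse token")
        self.num_tokens = num_tokens
        self.embed_dim = embed_dim
        hidden = 2 * num_tokens * embed_dim
        self.fc1 = Linear(fused_channels, hidden, rng)
        self.fc2 = Linear(hidden, num_tokens * embed_dim, rng)

    def forward(self, fused: FusedFeature) -> Tensor:
        pooled = global_avg_pool(fused.fused)          # (N, C)
        tokens = self.fc2(self.fc1(pooled).relu())     # (N, K*D)
        n = tokens.shape[0]
        return tokens.reshape(n, self.num_tokens, self.embed_dim)


class BoxTokenizer(Module):
    """Two tokens per box: sinusoidal encoding of each corner (normalized by
    the image size) plus a learned corner-type embedding."""

    def __init__(self, embed_dim: int, image_size: int, rng: np.random.Generator):
        self.embed_dim = embed_dim
        self.image_size = image_size
        self.corner_embed = Parameter(rng.normal(0, 0.02, size=(2, embed_dim)))

    def forward(self, boxes: list[Box]) -> Tensor:
        corners = []
        for b in boxes:
            lo = np.array([b.xmin, b.ymin])
            hi = np.array([b.xmax, b.ymax])
            if (lo < 0).any() or (hi > self.image_size).any():
                warnings.warn("box outside image bounds; clamping", stacklevel=2)
                lo = np.clip(lo, 0, self.image_size)
                hi = np.clip(hi, 0, self.image_size)
            corners.append(lo / self.image_size)
            corners.append(hi / self.image_size)
        pe = sinusoidal_position_encoding(np.asarray(corners), self.embed_dim)
        types = np.tile(np.arange(2), len(boxes))
        tokens = Tensor(pe) + self.corner_embed[types]
        return tokens  # (2*n_boxes, D)


def inject_dense(z_img: Tensor, p_dense: Tensor, alpha) -> Tensor:
    """Residual injection Z_cond = Z_img + alpha * P_dense."""
    if z_img.shape != p_dense.shape:
        raise ValueError(f"shape mismatch: {z_img.shape} vs {p_dense.shape}")
    return z_img + alpha * p_dense


class PromptEncoder(Module):
    """Bundle the fusion block, dense head, sparse head and gate.

    `use_dense` / `use_sparse` select the prompt-mode ablation arm; the gate
    alpha starts at exactly 0 so the conditioned embedding equals the plain
    embedding at initialization.
    """

    def __init__(self, pyramid_channels: tuple[int, int, int],
                 fused_channels: int, embed_dim: int, num_sparse_tokens: int,
                 rng: np.random.Generator,
                 use_dense: bool = True, use_sparse: bool = True):
        self.use_dense = use_dense
        self.use_sparse = use_sparse
        self.fuser = PyramidFuser(pyramid_channels, fused_channels, rng)
        if use_dense:
            self.dense_head = DenseHead(fused_channels, embed_dim, rng)
            self.alpha = Parameter(np.zeros(()))
            # the zero-initialized scalar gate is a saddle (dense-head
            # gradients scale with alpha); a larger per-parameter step lets
            # the gate engage within a miniature training budget
            self.alpha.lr_scale = 10.0
        if use_sparse:
            self.sparse_head = SparseHead(fused_channels, embed_dim,
                                          num_sparse_tokens, rng)

    def forward(self, pyr: FeaturePyramid) -> PromptBundle:
        fused = self.fuser(pyr)
        dense = self.dense_head(fused) if self.use_dense else None
        alpha = self.alpha if self.use_dense else None
        sparse = self.sparse_head(fused) if self.use_sparse else None
        return PromptBundle(dense=dense, alpha=alpha, sparse=sparse,
                            box_tokens=None)
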