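"""Module/parameter containers and the small set of layers the miniature
models are built from."""

from __future__ import annotations

import numpy as np

from .functional import conv2d
from .tensor import Tensor, softmax

__all__ = [
    "Parameter", "Module", "Linear", "Conv2d", "LayerNorm",
    "MultiheadAttention", "Sequential", "ReLU",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Lightweight parameter container with recursive discovery."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def trainable_parameters(self):
        return [p for p in self.parameters() if p.requires_grad]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def freeze(self):
        for p in self.parameters():
            p.requires_grad = False
        return self

    def unfreeze(self):
        for p in self.parameters():
            p.requires_grad = True
        return self

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        if zero_init:
            self.weight = Parameter(np.zeros((in_dim, out_dim)))
        else:
            self.weight = Parameter(_he_init(rng, (in_dim, out_dim), in_dim))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, pad_mode: str = "zeros",
                 bias: bool = True, zero_init: bool = False):
        fan_in = in_ch * kernel * kernel
        if zero_init:
            self.weight = Parameter(np.zeros((out_ch, in_ch, kernel, kernel)))
        else:
            self.weight = Parameter(_he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = padding
        self.pad_mode = pad_mode

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, pad_mode=self.pad_mode)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        m = x.mean(axis=-1, keepdims=True)
        centered = x - m
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered * ((var + self.eps) ** -0.5)
        return normed * self.gamma + self.beta


class MultiheadAttention(Module):
    """Standard scaled dot-product attention over (N, T, D) token sets."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 zero_out: bool = False):
        if dim % heads != 0:
            raise ValueError("dim must be divisible by heads")
        self.heads = heads
        self.dim = dim
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        # zero-init output projection: the residual stream starts unmodified
        # and attention contributions grow only as training demands them
        self.wo = Linear(dim, dim, rng, zero_init=zero_out)

    def forward(self, queries: Tensor, keys_values: Tensor,
                q_pe: Tensor | None = None, kv_pe: Tensor | None = None) -> Tensor:
        """Positional encodings (if given) enter the query/key projections
        only; the value/residual stream stays content-only."""
        n, t, d = queries.shape
        s = keys_values.shape[1]
        h, dk = self.heads, d // self.heads
        q_in = queries if q_pe is None else queries + q_pe
        k_in = keys_values if kv_pe is None else keys_values + kv_pe
        q = self.wq(q_in).reshape(n, t, h, dk).transpose(0, 2, 1, 3)
        k = self.wk(k_in).reshape(n, s, h, dk).transpose(0, 2, 1, 3)
        v = self.wv(keys_values).reshape(n, s, h, dk).transpose(0, 2, 1, 3)
        att = (q @ k.transpose(0, 1, 3, 2)) * (dk ** -0.5)
        att = softmax(att, axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.wo(out)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
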