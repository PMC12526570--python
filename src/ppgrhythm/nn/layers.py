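"""Trainable layers on top of the autodiff engine.

Weight matrices use He-normal initialization (std = sqrt(2 / fan_in)),
biases start at zero.  Every layer accepts and returns tensors shaped
[batch, time, channels]; dense layers also take [batch, features].
"""

from __future__ import annotations

import numpy as np

from ..exceptions import InvalidParameterError, ShapeError
from . import autograd
from .autograd import Tensor, concat, softmax

__all__ = [
    "Parameter", "Module", "Dense", "Conv1D", "DepthwiseConv1D", "MaxPool1D",
    "BatchNorm", "LayerNorm", "Dropout", "SpatialDropout1D", "LSTM", "BiLSTM",
    "MultiHeadAttention", "ResidualLayerNorm", "ChannelAttention",
    "GatedFusion",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters always track grads


def he_normal(rng: np.random.Generator, shape: tuple[int, ...],
              fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Module:
    """Base class: recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def _set_mode(self, mode: bool) -> None:
        self.training = mode
        for val in vars(self).values():
            if isinstance(val, Module):
                val._set_mode(mode)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item._set_mode(mode)

    def train(self) -> "Module":
        self._set_mode(True)
        return self

    def eval(self) -> "Module":
        self._set_mode(False)
        return self

    # -- checkpointing ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, arr in self._named_buffers():
            state[f"buffer:{name}"] = arr.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            if name not in state:
                raise KeyError(f"missing parameter {name} in state dict")
            if state[name].shape != p.data.shape:
                raise ShapeError(
                    f"shape mismatch for {name}: "
                    f"{state[name].shape} vs {p.data.shape}")
            p.data = state[name].astype(np.float64).copy()
        for name, arr in self._named_buffers():
            key = f"buffer:{name}"
            if key in state:
                arr[...] = state[key]

    def _named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Module):
                yield from val._named_buffers(f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item._named_buffers(f"{key}.{i}.")
            elif isinstance(val, np.ndarray) and name.startswith("running_"):
                yield key, val


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.w = Parameter(he_normal(rng, (n_in, n_out), n_in))
        self.b = Parameter(np.zeros(n_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.w
        if self.b is not None:
            y = y + self.b
        return y


class Conv1D(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, padding: str = "same"):
        super().__init__()
        self.padding = padding
        self.w = Parameter(he_normal(rng, (kernel, c_in, c_out),
                                     kernel * c_in))
        self.b = Parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        return autograd.conv1d(x, self.w, self.b, padding=self.padding)


class DepthwiseConv1D(Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        w = (np.zeros((kernel, channels)) if zero_init
             else he_normal(rng, (kernel, channels), kernel))
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        return autograd.depthwise_conv1d(x, self.w, self.b)


class MaxPool1D(Module):
    def __init__(self, size: int):
        super().__init__()
        self.size = size

    def forward(self, x: Tensor) -> Tensor:
        return autograd.maxpool1d(x, self.size)


class BatchNorm(Module):
    """Per-channel normalization over (batch, time); running statistics are
    used in inference mode."""

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 1), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 1), keepdims=True)
            m = self.momentum
            self.running_mean = (m * self.running_mean
                                 + (1 - m) * mu.data.reshape(-1))
            self.running_var = (m * self.running_var
                                + (1 - m) * var.data.reshape(-1))
            inv = (var + self.eps) ** -0.5
            return xc * inv * self.gamma + self.beta
        xc = x - self.running_mean
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return xc * inv * self.gamma + self.beta


class LayerNorm(Module):
    """Normalization over the channel axis; the pre-affine output of each
    row has mean 0 and unit variance (eps = 1e-5)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def normalized(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5)

    def forward(self, x: Tensor) -> Tensor:
        return self.normalized(x) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise InvalidParameterError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0:
            return x
        keep = 1.0 - self.rate
        mask = self.rng.binomial(1, keep, size=x.shape) / keep
        return x * Tensor(mask)


class SpatialDropout1D(Module):
    """Channel-wise dropout: drops whole feature maps, as used inside the
    residual convolution blocks."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0:
            return x
        keep = 1.0 - self.rate
        b, _, c = x.shape
        mask = self.rng.binomial(1, keep, size=(b, 1, c)) / keep
        return x * Tensor(mask)


class LSTM(Module):
    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator,
                 reverse: bool = False):
        super().__init__()
        self.wx = Parameter(he_normal(rng, (c_in, 4 * hidden), c_in))
        self.wh = Parameter(he_normal(rng, (hidden, 4 * hidden), hidden))
        self.b = Parameter(np.zeros(4 * hidden))
        self.reverse = reverse

    def forward(self, x: Tensor) -> Tensor:
        return autograd.lstm(x, self.wx, self.wh, self.b,
                             reverse=self.reverse)


class BiLSTM(Module):
    """Bidirectional LSTM returning the full sequence with forward and
    backward hidden states concatenated on the channel axis."""

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = LSTM(c_in, hidden, rng, reverse=False)
        self.bwd = LSTM(c_in, hidden, rng, reverse=True)

    def forward(self, x: Tensor) -> Tensor:
        return concat([self.fwd(x), self.bwd(x)], axis=-1)


def scaled_dot_attention_t(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """Tensor-graph scaled dot-product attention (numpy reference version
    with explicit weights lives in :mod:`ppgrhythm.attention`)."""
    dk = q.shape[-1]
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)
              ) * (1.0 / np.sqrt(dk))
    return softmax(scores, axis=-1) @ v


class MultiHeadAttention(Module):
    """Multi-head scaled dot-product attention with learned projections.

    Per-head projections are stored as full d_model x d_model matrices
    (head i occupies columns [i*d_k, (i+1)*d_k)); the concatenated heads
    pass through the output projection W^O.  Dropout is applied to the
    attention weights in training mode.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 dropout: float = 0.0, d_kv_in: int | None = None):
        super().__init__()
        if d_model % n_heads:
            raise InvalidParameterError(
                f"d_model {d_model} not divisible by n_heads {n_heads}")
        d_kv_in = d_model if d_kv_in is None else d_kv_in
        self.h = n_heads
        self.d_model = d_model
        self.wq = Dense(d_model, d_model, rng)
        self.wk = Dense(d_kv_in, d_model, rng)
        self.wv = Dense(d_kv_in, d_model, rng)
        self.wo = Dense(d_model, d_model, rng)
        self.drop = Dropout(dropout, rng)

    def _split(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        return (x.reshape(b, t, self.h, self.d_model // self.h)
                .transpose(0, 2, 1, 3))                    # [B, H, T, dk]

    def forward(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        if k.shape[-2] != v.shape[-2]:
            raise ShapeError("key and value must share row count")
        b, tq, _ = q.shape
        qh = self._split(self.wq(q))
        kh = self._split(self.wk(k))
        vh = self._split(self.wv(v))
        dk = self.d_model // self.h
        scores = (qh @ kh.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
        weights = self.drop(softmax(scores, axis=-1))
        out = weights @ vh                                  # [B, H, Tq, dk]
        out = out.transpose(0, 2, 1, 3).reshape(b, tq, self.d_model)
        return self.wo(out)


class ResidualLayerNorm(Module):
    """Y = LayerNorm(sublayer_output + X) over the channel axis."""

    def __init__(self, dim: int):
        super().__init__()
        self.norm = LayerNorm(dim)

    def forward(self, x: Tensor, sublayer_output: Tensor) -> Tensor:
        if x.shape != sublayer_output.shape:
            raise ShapeError(
                f"residual shapes differ: {x.shape} vs {sublayer_output.shape}")
        return self.norm(sublayer_output + x)


class ChannelAttention(Module):
    """Squeeze-and-excitation gate: global average over time, bottleneck
    with ReLU, expansion with sigmoid, per-channel multiplication."""

    def __init__(self, channels: int, reduction: int,
                 rng: np.random.Generator):
        super().__init__()
        if reduction > channels:
            raise InvalidParameterError(
                f"reduction {reduction} exceeds channel count {channels}")
        self.squeeze = Dense(channels, channels // reduction, rng)
        self.expand = Dense(channels // reduction, channels, rng)

    def gates(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=1)                              # [B, C]
        return self.expand(self.squeeze(pooled).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        g = self.gates(x)
        b, c = g.shape
        return x * g.reshape(b, 1, c)


class GatedFusion(Module):
    """Convex, learnable combination of two aligned feature streams:
    z = sigmoid(W [a || b]); out = z * a + (1 - z) * b."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.gate = Dense(2 * dim, dim, rng)

    def forward(self, a: Tensor, b: Tensor) -> Tensor:
        if a.shape != b.shape:
            raise ShapeError(f"fusion shapes differ: {a.shape} vs {b.shape}")
        z = self.gate(concat([a, b], axis=-1)).sigmoid()
        return z * a + (1.0 - z) * b
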