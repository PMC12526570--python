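"""Attention primitives.

``scaled_dot_attention`` is a pure numpy reference of the scaled
dot-product rule — softmax(Q K^T / sqrt(d_k)) V — returning both the output
and the row-stochastic weight matrix.  The trainable building blocks
(multi-head attention with learned projections, the residual layer-norm
wrapper, squeeze-excite channel attention, and the GRU-inspired sigmoid
fusion gate) are the autodiff modules from :mod:`ppgrhythm.nn`, re-exported
here together with their configuration type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError, ShapeError
from .nn.layers import (  # noqa: F401  (public surface)
    ChannelAttention,
    GatedFusion,
    MultiHeadAttention,
    ResidualLayerNorm,
)

__all__ = [
    "AttentionConfig",
    "scaled_dot_attention",
    "MultiHeadAttention",
    "ResidualLayerNorm",
    "ChannelAttention",
    "GatedFusion",
]


@dataclass(frozen=True)
class AttentionConfig:
    """Multi-head attention hyperparameters (4 parallel heads by default,
    dropout 0.2 on attention weights during training)."""

    d_model: int = 64
    n_heads: int = 4
    dropout: float = 0.2

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads

    def validate(self) -> None:
        if self.d_model % self.n_heads:
            raise InvalidParameterError(
                f"d_model {self.d_model} must be divisible by "
                f"n_heads {self.n_heads}")
        if not 0 <= self.dropout < 1:
            raise InvalidParameterError("dropout must be in [0, 1)")


def scaled_dot_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product attention on plain arrays.

    Returns ``(output, weights)`` where ``weights`` is the row-softmax of
    Q K^T / sqrt(d_k) (each row sums to 1) and ``output = weights @ V``.
    The softmax is stabilized by row-max subtraction.
    """
    q = np.asarray(q, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if q.shape[-1] != k.shape[-1]:
        raise ShapeError(
            f"query/key dims differ: {q.shape[-1]} vs {k.shape[-1]}")
    if k.shape[-2] != v.shape[-2]:
        raise ShapeError(
            f"key/value row counts differ: {k.shape[-2]} vs {v.shape[-2]}")
    dk = q.shape[-1]
    scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(dk)
    scores = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    weights = e / e.sum(axis=-1, keepdims=True)
    return weights @ v, weights
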