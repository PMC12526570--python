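"""Minimal reverse-mode automatic differentiation over numpy arrays.

Defines a :class:`Tensor` wrapping an ``ndarray`` and recording, for each
operation, a closure that pushes the output gradient back to its parents.
``backward()`` runs the closures in reverse topological order.  Broadcasting
is supported everywhere by summing gradients over broadcast axes.

Recurrent and convolutional primitives (``lstm``, ``conv1d``,
``depthwise_conv1d``, ``maxpool1d``) are fused ops with hand-written
backward passes, vectorized over the batch axis — the time loop of the LSTM
is the only per-step Python loop in the stack.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "no_grad", "concat", "softmax", "lstm", "conv1d",
           "depthwise_conv1d", "maxpool1d"]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference speed / memory)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes numpy broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (gs, ss) in enumerate(zip(grad.shape, shape)):
        if ss == 1 and gs != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _grad_enabled
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data: np.ndarray, parents: Iterable["Tensor"],
              backward: Callable[["Tensor"], None] | None) -> "Tensor":
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        req = _grad_enabled and any(p.requires_grad for p in parents)
        out = Tensor(data)
        out.requires_grad = req
        if req:
            out._parents = parents
            # stored uncurried (called as _backward(node)) so the closure
            # never references its own tensor: graphs stay cycle-free and
            # are freed by reference counting, not the cycle collector
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        a, b = self, Tensor._lift(other)

        def back(out):
            if a.requires_grad:
                a._accumulate(_unbroadcast(out.grad, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(out.grad, b.shape))
        return Tensor._make(a.data + b.data, (a, b), back)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def back(out):
            a._accumulate(-out.grad)
        return Tensor._make(-a.data, (a,), back)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)

        def back(out):
            if a.requires_grad:
                a._accumulate(_unbroadcast(out.grad * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(out.grad * a.data, b.shape))
        return Tensor._make(a.data * b.data, (a, b), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)

        def back(out):
            if a.requires_grad:
                a._accumulate(_unbroadcast(out.grad / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(
                    -out.grad * a.data / (b.data ** 2), b.shape))
        return Tensor._make(a.data / b.data, (a, b), back)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        a, e = self, float(exponent)

        def back(out):
            a._accumulate(out.grad * e * a.data ** (e - 1))
        return Tensor._make(a.data ** e, (a,), back)

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)

        def back(out):
            g = out.grad
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.shape))
        return Tensor._make(a.data @ b.data, (a, b), back)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        a = self
        y = np.exp(a.data)

        def back(out):
            a._accumulate(out.grad * y)
        return Tensor._make(y, (a,), back)

    def log(self):
        a = self

        def back(out):
            a._accumulate(out.grad / a.data)
        return Tensor._make(np.log(a.data), (a,), back)

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        a = self
        y = np.tanh(a.data)

        def back(out):
            a._accumulate(out.grad * (1 - y ** 2))
        return Tensor._make(y, (a,), back)

    def sigmoid(self):
        a = self
        y = 1.0 / (1.0 + np.exp(-a.data))

        def back(out):
            a._accumulate(out.grad * y * (1 - y))
        return Tensor._make(y, (a,), back)

    def relu(self):
        a = self
        mask = a.data > 0

        def back(out):
            a._accumulate(out.grad * mask)
        return Tensor._make(a.data * mask, (a,), back)

    # -- reductions / shaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def back(out):
            g = out.grad
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a_mod(axes, a.ndim)):
                    g = np.expand_dims(g, ax)
            a._accumulate(np.broadcast_to(g, a.shape).copy())
        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), back)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def back(out):
            a._accumulate(out.grad.reshape(a.shape))
        return Tensor._make(a.data.reshape(shape), (a,), back)

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def back(out):
            a._accumulate(out.grad.transpose(inv))
        return Tensor._make(a.data.transpose(axes), (a,), back)

    def __getitem__(self, idx):
        a = self

        def back(out):
            g = np.zeros_like(a.data)
            np.add.at(g, idx, out.grad)
            a._accumulate(g)
        return Tensor._make(a.data[idx], (a,), back)

    def broadcast_to(self, shape):
        a = self

        def back(out):
            a._accumulate(_unbroadcast(out.grad, a.shape))
        return Tensor._make(np.broadcast_to(a.data, shape).copy(), (a,), back)

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor without grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (LSTM over time)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = (np.ones_like(self.data) if grad is None
                     else np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node)


def a_mod(axes: tuple[int, ...], ndim: int) -> tuple[int, ...]:
    return tuple(ax % ndim for ax in axes)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def back(out):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(out.grad[tuple(sl)])
    return Tensor._make(np.concatenate(datas, axis=axis), tensors, back)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stabilized softmax (row-max subtraction; the shift is a
    constant with respect to the gradient)."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def back(out):
        g = out.grad
        x._accumulate(y * (g - (g * y).sum(axis=axis, keepdims=True)))
    return Tensor._make(y, (x,), back)


# ---------------------------------------------------------------------------
# fused ops

def conv1d(x: Tensor, w: Tensor, b: Tensor | None,
           padding: str = "same") -> Tensor:
    """1-D convolution (cross-correlation), stride 1.

    ``x``: [B, T, Cin]; ``w``: [K, Cin, Cout]; output [B, T, Cout].
    ``padding='same'`` pads symmetrically, ``'causal'`` pads on the left
    only so output t never sees input beyond t.
    """
    B, T, Ci = x.data.shape
    K, _, Co = w.data.shape
    if padding == "causal":
        pl, pr = K - 1, 0
    elif padding == "same":
        pl = (K - 1) // 2
        pr = K - 1 - pl
    else:
        raise ValueError(f"unknown padding {padding!r}")
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    idx = np.arange(T)[:, None] + np.arange(K)[None, :]      # [T, K]
    cols = xp[:, idx, :]                                     # [B, T, K, Ci]
    cols2 = cols.reshape(B, T, K * Ci)
    wr = w.data.reshape(K * Ci, Co)
    y = cols2 @ wr
    if b is not None:
        y = y + b.data

    def back(out):
        g = out.grad                                         # [B, T, Co]
        if w.requires_grad:
            gw = np.einsum("btf,btc->fc", cols2, g)
            w._accumulate(gw.reshape(K, Ci, Co))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1)))
        if x.requires_grad:
            gcols = (g @ wr.T).reshape(B, T, K, Ci)
            gxp = np.zeros_like(xp)
            np.add.at(gxp, (slice(None), idx, slice(None)), gcols)
            x._accumulate(gxp[:, pl: pl + T, :])
    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(y, parents, back)


def depthwise_conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Depthwise 1-D convolution with same-padding.

    ``x``: [B, T, C]; ``w``: [K, C] (one kernel per channel)."""
    B, T, C = x.data.shape
    K = w.data.shape[0]
    pl = (K - 1) // 2
    pr = K - 1 - pl
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    idx = np.arange(T)[:, None] + np.arange(K)[None, :]
    cols = xp[:, idx, :]                                     # [B, T, K, C]
    y = np.einsum("btkc,kc->btc", cols, w.data)
    if b is not None:
        y = y + b.data

    def back(out):
        g = out.grad
        if w.requires_grad:
            w._accumulate(np.einsum("btkc,btc->kc", cols, g))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1)))
        if x.requires_grad:
            gcols = g[:, :, None, :] * w.data[None, None, :, :]
            gxp = np.zeros_like(xp)
            np.add.at(gxp, (slice(None), idx, slice(None)), gcols)
            x._accumulate(gxp[:, pl: pl + T, :])
    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(y, parents, back)


def maxpool1d(x: Tensor, size: int) -> Tensor:
    """Non-overlapping temporal max pooling; trailing remainder dropped."""
    B, T, C = x.data.shape
    To = T // size
    xt = x.data[:, : To * size, :].reshape(B, To, size, C)
    arg = xt.argmax(axis=2)                                   # [B, To, C]
    y = np.take_along_axis(xt, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def back(out):
        gx = np.zeros((B, To, size, C))
        np.put_along_axis(gx, arg[:, :, None, :], out.grad[:, :, None, :],
                          axis=2)
        full = np.zeros_like(x.data)
        full[:, : To * size, :] = gx.reshape(B, To * size, C)
        x._accumulate(full)
    return Tensor._make(y, (x,), back)


def lstm(x: Tensor, wx: Tensor, wh: Tensor, b: Tensor,
         reverse: bool = False) -> Tensor:
    """Single-direction LSTM returning the full hidden sequence.

    ``x``: [B, T, Cin]; ``wx``: [Cin, 4H]; ``wh``: [H, 4H]; ``b``: [4H].
    Gate order along the 4H axis is (input, forget, cell, output).
    ``reverse=True`` runs right-to-left and returns the output re-aligned
    to the input's time order, so a bidirectional pair can be concatenated.
    """
    X = x.data[:, ::-1, :] if reverse else x.data
    B, T, Ci = X.shape
    H = wh.data.shape[0]
    zx = X @ wx.data                                          # [B, T, 4H]
    i_s = np.empty((B, T, H)); f_s = np.empty((B, T, H))
    g_s = np.empty((B, T, H)); o_s = np.empty((B, T, H))
    c_s = np.empty((B, T, H)); h_s = np.empty((B, T, H))
    tanh_c = np.empty((B, T, H))
    h_prev = np.zeros((B, H)); c_prev = np.zeros((B, H))
    Wh = wh.data; bb = b.data
    for t in range(T):
        z = zx[:, t] + h_prev @ Wh + bb
        i = 1 / (1 + np.exp(-z[:, :H]))
        f = 1 / (1 + np.exp(-z[:, H:2 * H]))
        g = np.tanh(z[:, 2 * H:3 * H])
        o = 1 / (1 + np.exp(-z[:, 3 * H:]))
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        i_s[:, t], f_s[:, t], g_s[:, t], o_s[:, t] = i, f, g, o
        c_s[:, t], h_s[:, t], tanh_c[:, t] = c, h, tc
        h_prev, c_prev = h, c
    out_data = h_s[:, ::-1, :] if reverse else h_s

    def back(out):
        G = out.grad[:, ::-1, :] if reverse else out.grad
        dWx = np.zeros_like(wx.data); dWh = np.zeros_like(Wh)
        db = np.zeros_like(bb); dX = np.zeros_like(X)
        dh_next = np.zeros((B, H)); dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            dh = G[:, t] + dh_next
            i, f, g, o = i_s[:, t], f_s[:, t], g_s[:, t], o_s[:, t]
            tc = tanh_c[:, t]
            do = dh * tc
            dc = dh * o * (1 - tc ** 2) + dc_next
            di = dc * g
            dg = dc * i
            cp = c_s[:, t - 1] if t > 0 else np.zeros((B, H))
            df = dc * cp
            dc_next = dc * f
            da = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g ** 2), do * o * (1 - o)], axis=1)  # [B, 4H]
            hp = h_s[:, t - 1] if t > 0 else np.zeros((B, H))
            dWx += X[:, t].T @ da
            dWh += hp.T @ da
            db += da.sum(axis=0)
            dX[:, t] = da @ wx.data.T
            dh_next = da @ Wh.T
        if wx.requires_grad:
            wx._accumulate(dWx)
        if wh.requires_grad:
            wh._accumulate(dWh)
        if b.requires_grad:
            b._accumulate(db)
        if x.requires_grad:
            x._accumulate(dX[:, ::-1, :] if reverse else dX)
    return Tensor._make(out_data, (x, wx, wh, b), back)
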