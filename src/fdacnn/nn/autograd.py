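"""Minimal reverse-mode automatic differentiation on numpy arrays.

The de-aliasing networks in this package are small enough to train on a
CPU, so rather than depending on a large deep-learning framework the
package carries its own tape-based autodiff engine: a :class:`Tensor`
wraps an ``ndarray`` and records the operations applied to it; calling
:meth:`Tensor.backward` on a scalar loss walks the tape in reverse
topological order and accumulates gradients.

Only the operations the reconstruction networks need are provided:
2-D convolution and transposed convolution, 2x2 max pooling, batch
normalisation, fixed-weight 2x bilinear upsampling, ReLU, sigmoid,
broadcasting multiply/add, channel concatenation and mean-squared error.
Convolutions are evaluated as a sum of per-kernel-offset BLAS matmuls,
which keeps both forward and backward passes vectorised.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "add",
    "mul",
    "relu",
    "sigmoid",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "maxpool2x2",
    "batch_norm2d",
    "upsample2x_bilinear",
    "mse",
]


class Tensor:
    """An ndarray plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        # first contribution owns a copy; later ones accumulate in place
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node; defaults to d(self)/d(self)=1."""
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(_topo_order(self)):
            if node._backward is not None:
                node._backward()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _topo_order(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _make(data: np.ndarray, parents: Sequence[Tensor], backward: Callable[[], None] | None) -> Tensor:
    out = Tensor(data)
    out.requires_grad = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise ops


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def _bw() -> None:
        if a.requires_grad:
            a._accum(_unbroadcast(out.grad, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(out.grad, b.data.shape))

    out = _make(out_data, (a, b), _bw)
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def _bw() -> None:
        if a.requires_grad:
            a._accum(_unbroadcast(out.grad * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(out.grad * a.data, b.data.shape))

    out = _make(out_data, (a, b), _bw)
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0)

    def _bw() -> None:
        x._accum(out.grad * mask)

    out = _make(out_data, (x,), _bw)
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def _bw() -> None:
        x._accum(out.grad * s * (1.0 - s))

    out = _make(s, (x,), _bw)
    return out


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = list(tensors)
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def _bw() -> None:
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(idx)])

    out = _make(out_data, ts, _bw)
    return out


# ---------------------------------------------------------------------------
# convolution family


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """NCHW convolution; ``w`` has shape (C_out, C_in, kh, kw)."""
    xd, wd = x.data, w.data
    n, c, _, _ = xd.shape
    c_out, c_in, kh, kw = wd.shape
    if c != c_in:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {c_in}")
    s, p = stride, padding
    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
    hp, wp = xp.shape[2:]
    ho = (hp - kh) // s + 1
    wo = (wp - kw) // s + 1
    if kh == 1 and kw == 1 and s == 1:
        out_flat = np.matmul(wd[:, :, 0, 0], xp.reshape(n, c, -1))
    else:
        out_flat = None
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i : i + (ho - 1) * s + 1 : s, j : j + (wo - 1) * s + 1 : s]
                term = np.matmul(wd[:, :, i, j], np.ascontiguousarray(xs).reshape(n, c, -1))
                if out_flat is None:
                    out_flat = term
                else:
                    out_flat += term
    out_data = out_flat.reshape(n, c_out, ho, wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def _bw() -> None:
        go = out.grad.reshape(n, c_out, ho * wo)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                sl_h = slice(i, i + (ho - 1) * s + 1, s)
                sl_w = slice(j, j + (wo - 1) * s + 1, s)
                if w.requires_grad:
                    xs = xp[:, :, sl_h, sl_w].reshape(n, c, -1)
                    gw_ij = np.matmul(go, xs.transpose(0, 2, 1)).sum(axis=0)
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[:, :, i, j] += gw_ij
                if x.requires_grad:
                    gxp[:, :, sl_h, sl_w] += np.matmul(wd[:, :, i, j].T, go).reshape(n, c, ho, wo)
        if x.requires_grad:
            x._accum(gxp[:, :, p : hp - p, p : wp - p] if p else gxp)
        if b is not None and b.requires_grad:
            b._accum(out.grad.sum(axis=(0, 2, 3)))

    out = _make(out_data, parents, _bw)
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 2, padding: int = 0) -> Tensor:
    """NCHW transposed convolution; ``w`` has shape (C_in, C_out, kh, kw)."""
    xd, wd = x.data, w.data
    n, c, h, wdt = xd.shape
    c_in, c_out, kh, kw = wd.shape
    if c != c_in:
        raise ValueError(f"conv_transpose2d: input has {c} channels, weight expects {c_in}")
    s, p = stride, padding
    hf = (h - 1) * s + kh
    wf = (wdt - 1) * s + kw
    outp = np.zeros((n, c_out, hf, wf), dtype=xd.dtype)
    x_flat = xd.reshape(n, c, -1)
    for i in range(kh):
        for j in range(kw):
            contrib = np.matmul(wd[:, :, i, j].T, x_flat).reshape(n, c_out, h, wdt)
            outp[:, :, i : i + (h - 1) * s + 1 : s, j : j + (wdt - 1) * s + 1 : s] += contrib
    out_data = outp[:, :, p : hf - p, p : wf - p] if p else outp
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def _bw() -> None:
        gop = np.pad(out.grad, ((0, 0), (0, 0), (p, p), (p, p))) if p else out.grad
        for i in range(kh):
            for j in range(kw):
                gos = gop[:, :, i : i + (h - 1) * s + 1 : s, j : j + (wdt - 1) * s + 1 : s]
                gos_flat = gos.reshape(n, c_out, -1)
                if x.requires_grad:
                    x._accum(np.matmul(wd[:, :, i, j], gos_flat).reshape(n, c, h, wdt))
                if w.requires_grad:
                    gw_ij = np.matmul(x_flat, gos_flat.transpose(0, 2, 1)).sum(axis=0)
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[:, :, i, j] += gw_ij
        if b is not None and b.requires_grad:
            b._accum(out.grad.sum(axis=(0, 2, 3)))

    out = _make(out_data, parents, _bw)
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    ho, wo = h // 2, w // 2
    xr = x.data.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def _bw() -> None:
        g4 = np.zeros((n, c, ho, wo, 4), dtype=x.data.dtype)
        np.put_along_axis(g4, idx[..., None], out.grad[..., None], axis=-1)
        gx = g4.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accum(gx)

    out = _make(out_data, (x,), _bw)
    return out


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation (NCHW). Running stats updated in place."""
    xd = x.data
    gshape = (1, -1, 1, 1)
    if training:
        mean = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    # fused affine: out = x*scale + shift with scale = gamma/std
    scale = (gamma.data * inv_std).reshape(gshape)
    shift = (beta.data - gamma.data * mean * inv_std).reshape(gshape)
    out_data = xd * scale + shift

    def _bw() -> None:
        go = out.grad
        xhat = (xd - mean.reshape(gshape)) * inv_std.reshape(gshape)
        if gamma.requires_grad:
            gamma._accum((go * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(go.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            if training:
                m = go.shape[0] * go.shape[2] * go.shape[3]
                mean_g = go.sum(axis=(0, 2, 3), keepdims=True) / m
                mean_gx = (go * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
                gx = (go - mean_g - xhat * mean_gx) * scale
            else:
                gx = go * scale
            x._accum(gx)

    out = _make(out_data, (x, gamma, beta), _bw)
    return out


_BILINEAR_TAPS = np.array([0.25, 0.75, 0.75, 0.25])


def _bilinear_norm(h: int, w: int, dtype) -> np.ndarray:
    """Per-pixel sum of bilinear tap weights (edge renormalisation map)."""
    ones = np.ones((1, 1, h, w), dtype=dtype)
    hf, wf = 2 * h + 2, 2 * w + 2
    acc = np.zeros((1, 1, hf, wf), dtype=dtype)
    for i in range(4):
        for j in range(4):
            acc[:, :, i : i + 2 * h - 1 : 2, j : j + 2 * w - 1 : 2] += _BILINEAR_TAPS[i] * _BILINEAR_TAPS[j] * ones
    return acc[:, :, 1 : hf - 1, 1 : wf - 1]


def upsample2x_bilinear(x: Tensor) -> Tensor:
    """Double the spatial size with fixed bilinear interpolation weights.

    A transposed convolution with the separable kernel outer([1,3,3,1]/4)
    at stride 2 and padding 1, with the tap weights renormalised at the
    borders so a constant map upsamples to exactly the same constant.
    """
    xd = x.data
    n, c, h, w = xd.shape
    hf, wf = 2 * h + 2, 2 * w + 2
    outp = np.zeros((n, c, hf, wf), dtype=xd.dtype)
    for i in range(4):
        for j in range(4):
            outp[:, :, i : i + 2 * h - 1 : 2, j : j + 2 * w - 1 : 2] += _BILINEAR_TAPS[i] * _BILINEAR_TAPS[j] * xd
    norm = _bilinear_norm(h, w, xd.dtype)
    out_data = outp[:, :, 1 : hf - 1, 1 : wf - 1] / norm

    def _bw() -> None:
        gop = np.pad(out.grad / norm, ((0, 0), (0, 0), (1, 1), (1, 1)))
        gx = np.zeros_like(xd)
        for i in range(4):
            for j in range(4):
                gx += _BILINEAR_TAPS[i] * _BILINEAR_TAPS[j] * gop[:, :, i : i + 2 * h - 1 : 2, j : j + 2 * w - 1 : 2]
        x._accum(gx)

    out = _make(out_data, (x,), _bw)
    return out


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target; returns a scalar Tensor."""
    diff = pred.data - np.asarray(target, dtype=pred.data.dtype)
    out_data = np.asarray((diff**2).mean(), dtype=pred.data.dtype)

    def _bw() -> None:
        pred._accum(out.grad * 2.0 * diff / diff.size)

    out = _make(out_data, (pred,), _bw)
    return out
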