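"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations needed by the temporal-attention networks in
this package: broadcast arithmetic, matmul, common nonlinearities, reductions,
shape manipulation, strided 3D convolution, dropout and a numerically stable
binary cross-entropy on logits.  Gradients are accumulated by reverse
topological traversal; correctness is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helper ------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff core ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        a, b = self, other

        def bwd(g):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._result(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        a, b = self, other

        def bwd(g):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._result(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        a, b = self, other
        inv = 1.0 / b.data

        def bwd(g):
            a._accum(_unbroadcast(g * inv, a.data.shape))
            b._accum(_unbroadcast(-g * a.data * inv * inv, b.data.shape))

        return Tensor._result(a.data * inv, (a, b), bwd)

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def bwd(g):
            a._accum(g * exponent * a.data ** (exponent - 1.0))

        return Tensor._result(out_data, (a,), bwd)

    def __matmul__(self, other):
        other = _as_tensor(other)
        a, b = self, other
        out_data = a.data @ b.data
        a_vec = a.data.ndim == 1
        b_vec = b.data.ndim == 1

        def bwd(g):
            ad = a.data[None, :] if a_vec else a.data
            bd = b.data[:, None] if b_vec else b.data
            g2 = g
            if a_vec:
                g2 = np.expand_dims(g2, -2)
            if b_vec:
                g2 = np.expand_dims(g2, -1)
            ga = _unbroadcast(g2 @ np.swapaxes(bd, -1, -2), ad.shape)
            gb = _unbroadcast(np.swapaxes(ad, -1, -2) @ g2, bd.shape)
            a._accum(ga[0] if a_vec else ga)
            b._accum(gb[:, 0] if b_vec else gb)

        return Tensor._result(out_data, (a, b), bwd)

    # -- shape --------------------------------------------------------------
    def reshape(self, *shape):
        a = self
        orig = a.data.shape

        def bwd(g):
            a._accum(g.reshape(orig))

        return Tensor._result(a.data.reshape(*shape), (a,), bwd)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def bwd(g):
            a._accum(g.transpose(*inv))

        return Tensor._result(a.data.transpose(*axes), (a,), bwd)

    def __getitem__(self, key):
        a = self

        def bwd(g):
            buf = np.zeros_like(a.data)
            buf[key] += g
            a._accum(buf)

        return Tensor._result(a.data[key], (a,), bwd)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        in_shape = a.data.shape

        def bwd(g):
            if axis is None:
                grad = np.broadcast_to(g, in_shape)
            else:
                axes = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, axes)
                grad = np.broadcast_to(g, in_shape)
            a._accum(np.ascontiguousarray(grad))

        return Tensor._result(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -----------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            a._accum(g * out_data)

        return Tensor._result(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            a._accum(g / a.data)

        return Tensor._result(np.log(a.data), (a,), bwd)

    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            a._accum(g * mask)

        return Tensor._result(a.data * mask, (a,), bwd)

    def sigmoid(self):
        a = self
        out_data = _sigmoid(a.data)

        def bwd(g):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor._result(out_data, (a,), bwd)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bwd(g):
            a._accum(g * (1.0 - out_data * out_data))

        return Tensor._result(out_data, (a,), bwd)

    def softplus(self):
        a = self
        out_data = np.logaddexp(0.0, a.data)

        def bwd(g):
            a._accum(g * _sigmoid(a.data))

        return Tensor._result(out_data, (a,), bwd)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# -- composite / custom operations ------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis` (max-shift is detached)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    return Tensor._result(out_data, tensors, bwd)


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accum(g[tuple(idx)])

    return Tensor._result(out_data, tensors, bwd)


def conv3d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """Strided 3D cross-correlation, NCDHW layout, cubic kernel.

    Forward runs as a single im2col matmul; the input gradient is scattered
    back with one strided slice-add per kernel offset (no per-voxel loops).
    """
    n, ci, d, h, wdt = x.data.shape
    co, ci_w, k, _, _ = w.data.shape
    if ci != ci_w:
        raise ValueError(f"channel mismatch: input {ci}, kernel {ci_w}")
    s, p = stride, padding
    patchify = (s == k and p == 0)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x.data
    do = (d + 2 * p - k) // s + 1
    ho = (h + 2 * p - k) // s + 1
    wo = (wdt + 2 * p - k) // s + 1
    if patchify:
        # non-overlapping windows: im2col is a pure reshape (no duplication)
        win = xp.reshape(n, ci, do, k, ho, k, wo, k)
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 5, 7, 2, 4, 6))
    else:
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 1, 5, 6, 7, 2, 3, 4))
    cols = cols.reshape(n, ci * k ** 3, do * ho * wo)
    w2 = w.data.reshape(co, ci * k ** 3)
    out_data = np.matmul(w2, cols).reshape(n, co, do, ho, wo)

    def bwd(g):
        gr = np.ascontiguousarray(g.reshape(n, co, do * ho * wo))
        if w.requires_grad:
            gw = np.einsum("nop,ncp->oc", gr, cols, optimize=True)
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            dcols = np.matmul(w2.T, gr).reshape(n, ci, k, k, k, do, ho, wo)
            if patchify:
                dx_full = dcols.transpose(0, 1, 5, 2, 6, 3, 7, 4).reshape(xp.shape)
                x._accum(np.ascontiguousarray(dx_full))
                return
            dxp = np.zeros_like(xp)
            for dz in range(k):
                for dy in range(k):
                    for dx in range(k):
                        dxp[:, :,
                            dz:dz + s * do:s,
                            dy:dy + s * ho:s,
                            dx:dx + s * wo:s] += dcols[:, :, dz, dy, dx]
            if p:
                dxp = dxp[:, :, p:p + d, p:p + h, p:p + wdt]
            x._accum(dxp)

    return Tensor._result(out_data, (x, w), bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = 1.0 - p
    mask = (rng.random(x.data.shape) < keep).astype(x.data.dtype) / keep

    def bwd(g):
        x._accum(g * mask)

    return Tensor._result(x.data * mask, (x,), bwd)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits; stable for large |logit|."""
    t = np.asarray(targets, dtype=logits.data.dtype)
    z = logits.data
    loss = np.mean(np.maximum(z, 0.0) - z * t + np.logaddexp(0.0, -np.abs(z)))

    def bwd(g):
        logits._accum(g * (_sigmoid(z) - t) / z.size)

    return Tensor._result(np.asarray(loss), (logits,), bwd)
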