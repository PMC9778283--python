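"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the delineation network needs: broadcasted
arithmetic, matmul, 1D convolution/pooling (im2col), axis reductions, ReLU,
sigmoid, concatenation and fused losses. Gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv1d",
    "avg_pool1d",
    "max_pool1d",
    "softmax_cross_entropy",
    "l1_loss",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an attached gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, name=""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        if not self.requires_grad:
            return
        grad = np.asarray(grad, dtype=np.float64)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def matmul(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bwd)

    __matmul__ = matmul

    # -- shape -----------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def bwd(g):
            self._accum(g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape))

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def amax(self, axis, keepdims=False):
        out = self.data.max(axis=axis, keepdims=True)

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            mask = (self.data == out)
            mask = mask / mask.sum(axis=axis, keepdims=True)
            self._accum(g * mask)

        return Tensor(out if keepdims else np.squeeze(out, axis=axis),
                      parents=(self,), backward=bwd)

    # -- nonlinearities --------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bwd)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def bwd(g):
            self._accum(g * out * (1.0 - out))

        return Tensor(out, parents=(self,), backward=bwd)

    def sqrt(self):
        out = np.sqrt(self.data)

        def bwd(g):
            self._accum(g * 0.5 / out)

        return Tensor(out, parents=(self,), backward=bwd)

    def abs(self):
        sign = np.sign(self.data)

        def bwd(g):
            self._accum(g * sign)

        return Tensor(np.abs(self.data), parents=(self,), backward=bwd)


def concat(tensors, axis):
    """Concatenate tensors along ``axis``; backward splits the gradient."""
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]

    def bwd(g):
        offs = np.cumsum([0] + sizes)
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._accum(g[tuple(idx)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bwd)


def _sliding_windows(xp: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """View of shape (N, C, K, L_out) onto padded input (N, C, Lp)."""
    n, c, lp = xp.shape
    l_out = (lp - kernel) // stride + 1
    s0, s1, s2 = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, (n, c, kernel, l_out), (s0, s1, s2, s2 * stride), writeable=False)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, pad=0):
    """1D cross-correlation; ``x`` (N, C_in, L), ``w`` (C_out, C_in, K)."""
    k = w.shape[2]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad))) if pad else x.data
    cols = _sliding_windows(xp, k, stride)
    out = np.einsum("ock,nckl->nol", w.data, cols, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None]
    l_out = out.shape[2]

    def bwd(g):
        if w.requires_grad:
            w._accum(np.einsum("nol,nckl->ock", g, cols, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.einsum("ock,nol->nckl", w.data, g, optimize=True)
            dxp = np.zeros_like(xp)
            for kk in range(k):
                dxp[:, :, kk:kk + l_out * stride:stride] += dcols[:, :, kk, :]
            x._accum(dxp[:, :, pad:dxp.shape[2] - pad] if pad else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents=parents, backward=bwd)


def avg_pool1d(x: Tensor, kernel: int, stride: int, pad: int = 0):
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad))) if pad else x.data
    cols = _sliding_windows(xp, kernel, stride)
    out = cols.mean(axis=2)
    l_out = out.shape[2]

    def bwd(g):
        dxp = np.zeros_like(xp)
        gk = g / kernel
        for kk in range(kernel):
            dxp[:, :, kk:kk + l_out * stride:stride] += gk
        x._accum(dxp[:, :, pad:dxp.shape[2] - pad] if pad else dxp)

    return Tensor(out, parents=(x,), backward=bwd)


def max_pool1d(x: Tensor, kernel: int, stride: int, pad: int = 0):
    if pad:
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)),
                    constant_values=-np.inf)
    else:
        xp = x.data
    cols = _sliding_windows(xp, kernel, stride)
    arg = cols.argmax(axis=2)
    out = np.take_along_axis(cols, arg[:, :, None, :], axis=2)[:, :, 0, :]
    l_out = out.shape[2]

    def bwd(g):
        dxp = np.zeros(xp.shape)
        n, c, _ = xp.shape
        ni, ci, li = np.meshgrid(np.arange(n), np.arange(c), np.arange(l_out),
                                 indexing="ij")
        np.add.at(dxp, (ni, ci, li * stride + arg), g)
        x._accum(dxp[:, :, pad:dxp.shape[2] - pad] if pad else dxp)

    return Tensor(out, parents=(x,), backward=bwd)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray):
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-300))

    def bwd(g):
        d = p.copy()
        d[np.arange(n), labels] -= 1.0
        logits._accum(g * d / n)

    return Tensor(loss, parents=(logits,), backward=bwd)


def l1_loss(pred: Tensor, target: np.ndarray):
    """Mean absolute error between ``pred`` and a constant target."""
    diff = pred.data - target
    sign = np.sign(diff)
    n = diff.size

    def bwd(g):
        pred._accum(g * sign / n)

    return Tensor(np.mean(np.abs(diff)), parents=(pred,), backward=bwd)
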