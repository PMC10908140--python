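"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it;
``Tensor.backward()`` walks the recorded graph in reverse topological order
and accumulates gradients.  Broadcasting is supported everywhere numpy
broadcasts; gradients of broadcast operands are summed back to the operand's
shape.

Only the operations the EEG architectures need are implemented: arithmetic,
matmul (batched), exp/log/sqrt, reductions (sum/mean/max), shape ops,
SELU/ReLU, length-preserving 1-D convolution, floor-mode max pooling, and a
fused softmax cross-entropy.  Everything runs in float64.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, prev=()):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in prev)
        self._backward = None
        self._prev = tuple(p for p in prev if p.requires_grad)

    # -- graph -------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=float))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * self._wrap(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self.pow(-1.0)

    def pow(self, p: float):
        out = Tensor(self.data ** p, prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1.0))

        out._backward = bwd
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bwd
        return out

    def sqrt(self):
        return self.pow(0.5)

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(np.matmul(self.data, other.data), prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = bwd
        return out

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), prev=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor(out_data, prev=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            od, gg = out_data, g
            if axis is not None and not keepdims:
                od = np.expand_dims(od, axis)
                gg = np.expand_dims(gg, axis)
            mask = (self.data == od)
            count = mask.sum(axis=axis if axis is not None else None, keepdims=True)
            self._accumulate(mask * gg / count)

        out._backward = bwd
        return out

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = bwd
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        out = Tensor(self.data.transpose(axes), prev=(self,))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], prev=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = bwd
        return out

    # -- activations ---------------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        out._backward = bwd
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


# -- functional ops ----------------------------------------------------------

SELU_LAMBDA = 1.0507009873554804934193349852946
SELU_ALPHA = 1.6732632423543772848170429916717


def selu(x: Tensor) -> Tensor:
    """Scaled exponential linear unit: λx for x>0, λα(exp(x)−1) otherwise."""
    pos = x.data > 0
    neg = np.minimum(x.data, 0.0)  # where() evaluates both branches
    out_data = np.where(pos, SELU_LAMBDA * x.data,
                        SELU_LAMBDA * SELU_ALPHA * np.expm1(neg))
    out = Tensor(out_data, prev=(x,))

    def bwd(g):
        if x.requires_grad:
            deriv = np.where(pos, SELU_LAMBDA,
                             SELU_LAMBDA * SELU_ALPHA * np.exp(neg))
            x._accumulate(g * deriv)

    out._backward = bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis` (max-shift is detached)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; fused forward/backward for stability.

    `labels` are integer class indices of shape [N].
    """
    labels = np.asarray(labels, dtype=int)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    log_probs = z - logsumexp
    n = labels.shape[0]
    loss_val = -log_probs[np.arange(n), labels].mean()
    out = Tensor(loss_val, prev=(logits,))

    def bwd(g):
        if logits.requires_grad:
            p = np.exp(log_probs)
            p[np.arange(n), labels] -= 1.0
            logits._accumulate(g * p / n)

    out._backward = bwd
    return out


def conv1d_same(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Length-preserving 1-D convolution (cross-correlation).

    x: [N, C_in, L]; w: [C_out, C_in, K]; b: [C_out].  Zero padding of
    (K-1)//2 on the left and K//2 on the right keeps the output length L.
    """
    n, c_in, length = x.shape
    c_out, c_in_w, k = w.shape
    if c_in != c_in_w:
        raise ValueError(f"channel mismatch: input {c_in}, kernel {c_in_w}")
    pad_l, pad_r = (k - 1) // 2, k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad_l, pad_r)))
    # im2col: [N, L, C_in*K]
    cols = np.empty((n, length, c_in * k))
    for j in range(k):
        cols[:, :, j::k] = xp[:, :, j:j + length].transpose(0, 2, 1)
    wmat = w.data.reshape(c_out, c_in * k)  # rows match cols layout (c, j)
    out_data = cols @ wmat.T + b.data  # [N, L, C_out]
    out_data = out_data.transpose(0, 2, 1)  # [N, C_out, L]
    out = Tensor(out_data, prev=(x, w, b))

    def bwd(g):
        gl = g.transpose(0, 2, 1)  # [N, L, C_out]
        if w.requires_grad:
            gw = np.einsum("nlo,nlc->oc", gl, cols)
            w._accumulate(gw.reshape(c_out, c_in, k))
        if b.requires_grad:
            b._accumulate(gl.sum(axis=(0, 1)))
        if x.requires_grad:
            gcols = gl @ wmat  # [N, L, C_in*K]
            gxp = np.zeros_like(xp)
            for j in range(k):
                gxp[:, :, j:j + length] += gcols[:, :, j::k].transpose(0, 2, 1)
            x._accumulate(gxp[:, :, pad_l:pad_l + length])

    out._backward = bwd
    return out


def maxpool1d(x: Tensor, size: int = 2) -> Tensor:
    """Floor-mode max pooling with stride == size over the last axis."""
    n, c, length = x.shape
    l_out = length // size
    if l_out < 1:
        raise ValueError(f"pooling length {length} below pool size {size}")
    trimmed = x.data[:, :, : l_out * size].reshape(n, c, l_out, size)
    out_data = trimmed.max(axis=3)
    out = Tensor(out_data, prev=(x,))

    def bwd(g):
        if not x.requires_grad:
            return
        mask = trimmed == out_data[..., None]
        # split ties evenly so gradient mass is conserved
        mask = mask / mask.sum(axis=3, keepdims=True)
        gx = np.zeros_like(x.data)
        gx[:, :, : l_out * size] = (mask * g[..., None]).reshape(n, c, l_out * size)
        x._accumulate(gx)

    out._backward = bwd
    return out
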