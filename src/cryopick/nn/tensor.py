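"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations the segmentation network and the per-image denoiser
need are implemented: elementwise arithmetic, matmul, 2D (transposed)
convolution, reductions, reshapes and a few activations. Gradients are
accumulated by topological traversal of the recorded graph.
"""

from __future__ import annotations

import numpy as np

from . import functional as F


class Tensor:
    """An array node in the autodiff graph.

    Parameters
    ----------
    data : array-like
        Stored as-is when already a floating numpy array, otherwise cast
        to float32.
    requires_grad : bool
        Mark as trainable leaf. Non-leaf tensors inherit the flag from
        their parents.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self):
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph machinery ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and t._backward is None:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- operators ------------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), power(self, -1.0))

    def __pow__(self, k):
        return power(self, k)

    def __getitem__(self, idx):
        return take(self, idx)

    # convenience methods
    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum grad over dims broadcast relative to ``shape``."""
    if grad.shape == tuple(shape):
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


# -- elementwise --------------------------------------------------------------

def add(a, b):
    a, b = _wrap(a), _wrap(b)
    out = a.data + b.data
    return Tensor(
        out,
        _parents=(a, b),
        _backward=lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    out = a.data * b.data
    return Tensor(
        out,
        _parents=(a, b),
        _backward=lambda g: (
            _unbroadcast(g * b.data, a.shape),
            _unbroadcast(g * a.data, b.shape),
        ),
    )


def power(a, k):
    a = _wrap(a)
    out = a.data**k
    return Tensor(
        out,
        _parents=(a,),
        _backward=lambda g: (g * k * a.data ** (k - 1),),
    )


def exp(a):
    a = _wrap(a)
    out = np.exp(a.data)
    return Tensor(out, _parents=(a,), _backward=lambda g: (g * out,))


def log(a):
    a = _wrap(a)
    return Tensor(
        np.log(a.data), _parents=(a,), _backward=lambda g: (g / a.data,)
    )


def clamp(a, lo, hi):
    a = _wrap(a)
    out = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)
    return Tensor(out, _parents=(a,), _backward=lambda g: (g * mask,))


def relu(a):
    a = _wrap(a)
    mask = a.data > 0
    return Tensor(a.data * mask, _parents=(a,), _backward=lambda g: (g * mask,))


def leaky_relu(a, slope=0.1):
    a = _wrap(a)
    mask = a.data > 0
    scale = np.where(mask, 1.0, slope).astype(a.data.dtype)
    return Tensor(a.data * scale, _parents=(a,), _backward=lambda g: (g * scale,))


def sigmoid(a):
    a = _wrap(a)
    out = 1.0 / (1.0 + np.exp(-a.data))
    return Tensor(
        out, _parents=(a,), _backward=lambda g: (g * out * (1.0 - out),)
    )


def gelu(a):
    """tanh-approximated GELU."""
    a = _wrap(a)
    c = np.sqrt(2.0 / np.pi).astype(a.data.dtype)
    x = a.data
    inner = c * (x + 0.044715 * x**3)
    t = np.tanh(inner)
    out = 0.5 * x * (1.0 + t)

    def bwd(g):
        dt = (1.0 - t**2) * c * (1.0 + 3 * 0.044715 * x**2)
        return (g * (0.5 * (1.0 + t) + 0.5 * x * dt),)

    return Tensor(out, _parents=(a,), _backward=bwd)


# -- reductions / shape ------------------------------------------------------

def reduce_sum(a, axis=None, keepdims=False):
    a = _wrap(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.shape).copy(),)

    return Tensor(out, _parents=(a,), _backward=bwd)


def reduce_mean(a, axis=None, keepdims=False):
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[i] for i in np.atleast_1d(axis)]
    )
    s = reduce_sum(a, axis, keepdims)
    return mul(s, 1.0 / float(n))


def reduce_max(a, axis, keepdims=False):
    a = _wrap(a)
    out = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == out).astype(a.data.dtype)
    mask = mask / mask.sum(axis=axis, keepdims=True)

    def bwd(g):
        g = np.asarray(g)
        if not keepdims:
            g = np.expand_dims(g, axis)
        return (g * mask,)

    return Tensor(out if keepdims else out.squeeze(axis), _parents=(a,), _backward=bwd)


def reshape(a, shape):
    a = _wrap(a)
    return Tensor(
        a.data.reshape(shape),
        _parents=(a,),
        _backward=lambda g: (g.reshape(a.shape),),
    )


def transpose(a, axes):
    a = _wrap(a)
    inv = np.argsort(axes)
    return Tensor(
        a.data.transpose(axes),
        _parents=(a,),
        _backward=lambda g: (g.transpose(inv),),
    )


def take(a, idx):
    a = _wrap(a)
    out = a.data[idx]

    def bwd(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        return (full,)

    return Tensor(out, _parents=(a,), _backward=bwd)


def concat(tensors, axis=1):
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)

    def bwd(g):
        return tuple(np.split(g, np.cumsum(sizes)[:-1], axis=axis))

    return Tensor(out, _parents=tuple(tensors), _backward=bwd)


def matmul(a, b):
    a, b = _wrap(a), _wrap(b)
    out = np.matmul(a.data, b.data)

    def bwd(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

    return Tensor(out, _parents=(a, b), _backward=bwd)


def softmax(a, axis=-1):
    m = reduce_max(a, axis=axis, keepdims=True)
    e = exp(add(a, mul(m, -1.0)))
    return mul(e, power(reduce_sum(e, axis=axis, keepdims=True), -1.0))


# -- convolution --------------------------------------------------------------

def conv2d(x, w, bias=None, stride=1, padding=0, dilation=1, groups=1):
    """2D cross-correlation, NCHW layout, grouped."""
    x, w = _wrap(x), _wrap(w)
    out = F.conv2d_forward(x.data, w.data, stride, padding, dilation, groups)

    def bwd(g):
        gx = (
            F.conv2d_input_grad(g, w.data, x.shape, stride, padding, dilation, groups)
            if x.requires_grad
            else None
        )
        gw = (
            F.conv2d_weight_grad(g, x.data, w.shape, stride, padding, dilation, groups)
            if w.requires_grad
            else None
        )
        return (gx, gw)

    y = Tensor(out, _parents=(x, w), _backward=bwd)
    if bias is not None:
        y = add(y, reshape(bias, (1, -1, 1, 1)))
    return y


def conv_transpose2d(x, w, stride=1, padding=0, dilation=1, groups=1, out_hw=None):
    """Transposed convolution; the kernel is treated as fixed (no weight grad)."""
    x, w = _wrap(x), _wrap(w)
    if w.requires_grad:
        raise NotImplementedError("conv_transpose2d supports fixed kernels only")
    out = F.conv_transpose2d_forward(
        x.data, w.data, stride, padding, dilation, groups, out_hw
    )

    def bwd(g):
        gx = F.conv2d_forward(g, w.data, stride, padding, dilation, groups)
        return (gx, None)

    return Tensor(out, _parents=(x, w), _backward=bwd)


def global_avg_pool(x):
    return reduce_mean(x, axis=(2, 3), keepdims=True)


def upsample_bilinear2x(x):
    """Factor-2 bilinear upsampling as a fixed transposed convolution.

    Border taps are renormalized (partition of unity) so constants are
    preserved exactly.
    """
    x = _wrap(x)
    c = x.shape[1]
    k1 = np.array([0.25, 0.75, 0.75, 0.25], dtype=x.data.dtype)
    k2 = np.outer(k1, k1)
    w = np.zeros((c, 1, 4, 4), dtype=x.data.dtype)
    w[:, 0] = k2
    wt = Tensor(w)
    y = conv_transpose2d(x, wt, stride=2, padding=1, groups=c)
    ones = np.ones((1, c, x.shape[2], x.shape[3]), dtype=x.data.dtype)
    norm = F.conv_transpose2d_forward(ones, w, stride=2, padding=1, groups=c)
    return mul(y, Tensor(1.0 / norm))


def upsample_to(x, hw):
    """Repeated bilinear ×2 until the target (power-of-two multiple) size."""
    out = x
    while out.shape[2] < hw[0]:
        out = upsample_bilinear2x(out)
    if out.shape[2] != hw[0] or out.shape[3] != hw[1]:
        raise ValueError(f"cannot upsample {x.shape} to {hw}")
    return out
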