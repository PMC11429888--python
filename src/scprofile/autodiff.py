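"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's trainable components (sequence encoder, low-rank adapters,
hypernetwork decoder) are small enough that a compact tape-based engine over
``numpy.ndarray`` is sufficient: tensors record their parents and a backward
closure, and :meth:`Tensor.backward` walks the tape in reverse topological
order. Broadcasting follows numpy semantics; gradients of broadcast operands
are summed back to the operand's shape.

Arithmetic is carried out in float32 (see ``DTYPE``), which is accurate
enough for training and halves memory traffic. Only the primitives the model needs are
implemented (element-wise algebra, matmul with batch broadcasting, reductions,
shape ops, erf/tanh/exp/log, 1-D convolution via im2col).
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp


DTYPE = np.float32  # engine precision: float32 is ~2x faster at these sizes


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, _parents=(), name: str = ""):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = None
        self.name = name

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd ----------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    @property
    def T(self):
        return transpose(self, None)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req, _parents=tuple(p for p in parents if p.requires_grad))
    if req:
        out._backward = backward
    return out


# -- element-wise ----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _wrap(a)
    out_data = a.data ** p

    def backward(g):
        a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), backward)


def texp(a) -> Tensor:
    a = _wrap(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def tlog(a) -> Tensor:
    a = _wrap(a)
    out_data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(out_data, (a,), backward)


def ttanh(a) -> Tensor:
    a = _wrap(a)
    out_data = np.tanh(a.data)

    def backward(g):
        a._accumulate(g * (1.0 - out_data ** 2))

    return _make(out_data, (a,), backward)


def terf(a) -> Tensor:
    a = _wrap(a)
    out_data = _sp.erf(a.data)

    def backward(g):
        a._accumulate(g * (2.0 / np.sqrt(np.pi)) * np.exp(-a.data ** 2))

    return _make(out_data, (a,), backward)


def gelu(a) -> Tensor:
    """Exact GELU: x * Phi(x) with the Gaussian CDF via erf."""
    a = _wrap(a)
    x = a.data
    phi = 0.5 * (1.0 + _sp.erf(x / np.sqrt(2.0)))
    out_data = x * phi

    def backward(g):
        pdf = np.exp(-0.5 * x ** 2) / np.sqrt(2.0 * np.pi)
        a._accumulate(g * (phi + x * pdf))

    return _make(out_data, (a,), backward)


def softplus(a) -> Tensor:
    """log(1 + exp(x)), numerically stable; derivative is the sigmoid."""
    a = _wrap(a)
    x = a.data
    out_data = np.logaddexp(0.0, x)

    def backward(g):
        a._accumulate(g * _sp.expit(x))

    return _make(out_data, (a,), backward)


# -- reductions / shape ----------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            grad = np.broadcast_to(g, a.shape)
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, tuple(ax % a.ndim for ax in axes))
            grad = np.broadcast_to(g, a.shape)
        a._accumulate(grad.copy() if not grad.flags.writeable else grad)

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    n = a.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes=None) -> Tensor:
    a = _wrap(a)
    out_data = np.transpose(a.data, axes)

    def backward(g):
        inv = None if axes is None else np.argsort(axes)
        a._accumulate(np.transpose(g, inv))

    return _make(out_data, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = _wrap(a)
    out_data = a.data[idx]

    def backward(g):
        grad = np.zeros_like(a.data)
        np.add.at(grad, idx, g)
        a._accumulate(grad)

    return _make(out_data, (a,), backward)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(out_data, tuple(tensors), backward)


def stack(tensors, axis=0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return _make(out_data, tuple(tensors), backward)


# -- linear algebra --------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.shape))

    return _make(out_data, (a, b), backward)


def softmax(a, axis=-1) -> Tensor:
    """Shift-stabilized softmax; the shift constant carries no gradient
    (softmax is shift-invariant, so this is exact)."""
    a = _wrap(a)
    shifted = add(a, Tensor(-a.data.max(axis=axis, keepdims=True)))
    e = texp(shifted)
    return e / tsum(e, axis=axis, keepdims=True)


# -- convolution -----------------------------------------------------------

def conv1d(x, weight, bias=None, pad: str = "same", stride: int = 1) -> Tensor:
    """1-D convolution over positions.

    x: (L, C_in); weight: (C_out, k*C_in) flattened taps (tap-major);
    bias: (C_out,). ``pad='same'`` zero-pads so L_out = L/stride (requires
    odd k and L divisible by stride); ``'valid'`` shrinks.
    """
    x, weight = _wrap(x), _wrap(weight)
    L, c_in = x.shape
    c_out = weight.shape[0]
    k = weight.shape[1] // c_in
    if pad == "same":
        if k % 2 == 0:
            raise ValueError("same-padding requires odd kernel size")
        p = (k - 1) // 2
        xp = np.pad(x.data, ((p, p), (0, 0)))
    elif pad == "valid":
        p = 0
        xp = x.data
    else:
        raise ValueError(f"unknown padding {pad!r}")
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=0)  # (L_out1, C, k)
    win = win[::stride]
    cols = np.ascontiguousarray(np.swapaxes(win, 1, 2)).reshape(win.shape[0], k * c_in)
    out_data = cols @ weight.data.T  # (L_out, c_out)
    if bias is not None:
        out_data = out_data + _wrap(bias).data

    bias_t = _wrap(bias) if bias is not None else None

    def backward(g):
        # g: (L_out, c_out)
        if weight.requires_grad:
            weight._accumulate(g.T @ cols)
        if bias_t is not None and bias_t.requires_grad:
            bias_t._accumulate(g.sum(axis=0))
        if x.requires_grad:
            gcols = g @ weight.data  # (L_out, k*c_in)
            gcols = gcols.reshape(g.shape[0], k, c_in)
            gx = np.zeros_like(xp)
            for tap in range(k):
                gx[tap:tap + stride * g.shape[0]:stride] += gcols[:, tap, :]
            if p:
                gx = gx[p:-p]
            x._accumulate(gx)

    parents = (x, weight) if bias is None else (x, weight, bias_t)
    return _make(out_data, parents, backward)


def batch_norm(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Fused batch normalization over axis 0 (positions) per channel."""
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    mu = x.data.mean(axis=0)
    var = x.data.var(axis=0)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = gamma.data * xhat + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=0))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=0))
        if x.requires_grad:
            gm = g.mean(axis=0)
            gxm = (g * xhat).mean(axis=0)
            x._accumulate(gamma.data * inv * (g - gm - xhat * gxm))

    return _make(out_data, (x, gamma, beta), backward)


def avg_pool(x, factor: int) -> Tensor:
    """Average-pool positions by an integer factor; x: (L, C)."""
    x = _wrap(x)
    L, C = x.shape
    if L % factor:
        raise ValueError(f"length {L} not divisible by pool factor {factor}")
    out_data = x.data.reshape(L // factor, factor, C).mean(axis=1)

    def backward(g):
        gx = np.repeat(g / factor, factor, axis=0)
        x._accumulate(gx)

    return _make(out_data, (x,), backward)
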