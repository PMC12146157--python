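"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: every operation builds a node
holding references to its parent tensors and a closure that maps the
output gradient to parent gradients.  ``Tensor.backward`` runs the tape
in reverse topological order.  Float32 throughout; broadcasting follows
numpy semantics with gradients summed back to the parent shape.

Only the operations the detector needs are provided: elementwise
arithmetic and transcendentals, reductions, shape ops, batched matmul,
zero-padded 2-D convolution (im2col), nearest 2x upsampling and integer
spatial shifts (the building block of snake-kernel sampling).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "concatenate",
    "maximum",
    "minimum",
    "conv2d",
    "shift_sample",
    "upsample_nearest2x",
]

_DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer mixed ndarray/Tensor arithmetic to our reflected ops
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- infrastructure ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=_DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free closures eagerly; the tape is single-use
            node._backward = None
            node._parents = ()

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad and not self._parents:
            return
        if self.grad is None:
            self.grad = g.astype(_DTYPE, copy=True)
        else:
            self.grad += g

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# -- elementwise arithmetic --------------------------------------------

def _binary(a, b, fwd, bwd_a, bwd_b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = fwd(a.data, b.data)

    def backward(g):
        a._accum(_unbroadcast(bwd_a(g, a.data, b.data), a.data.shape))
        b._accum(_unbroadcast(bwd_b(g, a.data, b.data), b.data.shape))

    return _node(data, (a, b), backward)


def _unary(a, fwd, bwd):
    a = _as_tensor(a)
    data = fwd(a.data)

    def backward(g):
        a._accum(bwd(g, a.data, data))

    return _node(data, (a,), backward)


def _add(a, b):
    return _binary(a, b, lambda x, y: x + y, lambda g, x, y: g, lambda g, x, y: g)


def _mul(a, b):
    return _binary(a, b, lambda x, y: x * y, lambda g, x, y: g * y, lambda g, x, y: g * x)


def _sub(a, b):
    return _binary(a, b, lambda x, y: x - y, lambda g, x, y: g, lambda g, x, y: -g)


def _div(a, b):
    return _binary(a, b, lambda x, y: x / y,
                   lambda g, x, y: g / y,
                   lambda g, x, y: -g * x / (y * y))


Tensor.__add__ = _add
Tensor.__radd__ = lambda self, other: _add(other, self)
Tensor.__mul__ = _mul
Tensor.__rmul__ = lambda self, other: _mul(other, self)
Tensor.__sub__ = _sub
Tensor.__rsub__ = lambda self, other: _sub(other, self)
Tensor.__truediv__ = _div
Tensor.__rtruediv__ = lambda self, other: _div(other, self)
Tensor.__neg__ = lambda self: _mul(self, -1.0)


def _pow(a, p: float):
    return _unary(a, lambda x: x ** p, lambda g, x, y: g * p * x ** (p - 1))


Tensor.__pow__ = _pow
Tensor.sqrt = lambda self: _pow(self, 0.5)
Tensor.exp = lambda self: _unary(self, np.exp, lambda g, x, y: g * y)
Tensor.log = lambda self: _unary(self, np.log, lambda g, x, y: g / x)
Tensor.arctan = lambda self: _unary(self, np.arctan, lambda g, x, y: g / (1.0 + x * x))
Tensor.abs = lambda self: _unary(self, np.abs, lambda g, x, y: g * np.sign(x))


def _sigmoid(a):
    return _unary(a, lambda x: 1.0 / (1.0 + np.exp(-x)), lambda g, x, y: g * y * (1.0 - y))


def _silu(a):
    def fwd(x):
        return x / (1.0 + np.exp(-x))

    def bwd(g, x, y):
        s = 1.0 / (1.0 + np.exp(-x))
        return g * (s + x * s * (1.0 - s))

    return _unary(a, fwd, bwd)


def _softplus(a):
    # numerically stable: log(1+e^x) = max(x,0) + log1p(e^{-|x|})
    def fwd(x):
        return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))

    def bwd(g, x, y):
        return g / (1.0 + np.exp(-x))

    return _unary(a, fwd, bwd)


Tensor.sigmoid = _sigmoid
Tensor.silu = _silu
Tensor.softplus = _softplus


def maximum(a, b):
    return _binary(a, b, np.maximum,
                   lambda g, x, y: g * (x >= y),
                   lambda g, x, y: g * (x < y))


def minimum(a, b):
    return _binary(a, b, np.minimum,
                   lambda g, x, y: g * (x <= y),
                   lambda g, x, y: g * (x > y))


def _clip(a, lo, hi):
    return minimum(maximum(a, lo), hi)


Tensor.clip = _clip


# -- reductions and shape ops ------------------------------------------

def _sum(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.data.shape).astype(_DTYPE))

    return _node(data, (a,), backward)


def _mean(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return _sum(a, axis=axis, keepdims=keepdims) * (1.0 / float(n))


Tensor.sum = _sum
Tensor.mean = _mean


def _reshape(a, *shape):
    a = _as_tensor(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    data = a.data.reshape(shape)
    orig = a.data.shape

    def backward(g):
        a._accum(g.reshape(orig))

    return _node(data, (a,), backward)


def _transpose(a, axes):
    a = _as_tensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        a._accum(g.transpose(inv))

    return _node(data, (a,), backward)


Tensor.reshape = _reshape
Tensor.transpose = _transpose


def _getitem(a, idx):
    a = _as_tensor(a)
    data = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accum(full)

    return _node(data, (a,), backward)


Tensor.__getitem__ = _getitem


def concatenate(tensors, axis=0):
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return _node(data, tuple(tensors), backward)


def _matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accum(_unbroadcast(ga, a.data.shape))
        b._accum(_unbroadcast(gb, b.data.shape))

    return _node(data, (a, b), backward)


Tensor.__matmul__ = _matmul


# -- spatial ops --------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Zero-padded 2-D cross-correlation.

    x: (N, Ci, H, W); w: (Co, Ci, kh, kw); b: (Co,) or None.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    N, Ci, H, W = x.data.shape
    Co, Ci2, kh, kw = w.data.shape
    if Ci != Ci2:
        raise ValueError(f"channel mismatch: input {Ci} vs kernel {Ci2}")
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::s, ::s]                      # (N,Ci,Ho,Wo,kh,kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N, Ho * Wo, Ci * kh * kw)
    W2 = w.data.reshape(Co, -1)
    y = cols @ W2.T                                # (N, Ho*Wo, Co)
    out_data = y.transpose(0, 2, 1).reshape(N, Co, Ho, Wo)
    if b is not None:
        b = _as_tensor(b)
        out_data = out_data + b.data.reshape(1, Co, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gy = g.reshape(N, Co, Ho * Wo).transpose(0, 2, 1)      # (N,P,Co)
        gW2 = np.einsum("npo,npk->ok", gy, cols)
        w._accum(gW2.reshape(w.data.shape))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        gcols = gy @ W2                                        # (N,P,Ci*kh*kw)
        gcols = gcols.reshape(N, Ho, Wo, Ci, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        gxp = np.zeros_like(xp)
        for a_ in range(kh):
            for b_ in range(kw):
                gxp[:, :, a_:a_ + s * Ho:s, b_:b_ + s * Wo:s] += gcols[..., a_, b_]
        gx = gxp[:, :, p:p + H, p:p + W] if p else gxp
        x._accum(gx)

    return _node(out_data, parents, backward)


def _shift_np(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """out[..., i, j] = a[..., i+dy, j+dx], zero outside the grid."""
    H, W = a.shape[-2:]
    out = np.zeros_like(a)
    ys = slice(max(0, dy), min(H, H + dy))         # source rows
    yd = slice(max(0, -dy), min(H, H - dy))        # destination rows
    xs = slice(max(0, dx), min(W, W + dx))
    xd = slice(max(0, -dx), min(W, W - dx))
    if ys.start < ys.stop and xs.start < xs.stop:
        out[..., yd, xd] = a[..., ys, xs]
    return out


def shift_sample(x: Tensor, dy: int, dx: int) -> Tensor:
    """Sample ``x`` at integer offset (dy, dx): out(i,j) = x(i+dy, j+dx)."""
    x = _as_tensor(x)
    data = _shift_np(x.data, dy, dx)

    def backward(g):
        x._accum(_shift_np(g, -dy, -dx))

    return _node(data, (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    data = x.data.repeat(2, axis=-2).repeat(2, axis=-1)
    N, C, H, W = x.data.shape

    def backward(g):
        x._accum(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    return _node(data, (x,), backward)
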