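"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine covering exactly the operations the
translation networks need: convolution, nearest-neighbour upsampling,
pointwise nonlinearities, instance normalisation, matrix products, reductions
and the cross-entropy head.  Arrays are kept in whatever float dtype the
caller supplies (float32 for training, float64 for gradient checks).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (forward-only mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self) = 1)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- operators
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs(*ts: Tensor) -> bool:
    return _GRAD_ENABLED and any(t.requires_grad for t in ts)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum `g` down to `shape` to undo NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------- ops
def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data
    if not _needs(a, b):
        return Tensor(out_data)
    out = Tensor(out_data, True, (a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data
    if not _needs(a, b):
        return Tensor(out_data)
    out = Tensor(out_data, True, (a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = backward
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data
    if not _needs(a, b):
        return Tensor(out_data)
    out = Tensor(out_data, True, (a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ np.swapaxes(b.data, -1, -2))
        if b.requires_grad:
            b._accumulate(np.swapaxes(a.data, -1, -2) @ g)

    out._backward = backward
    return out


def reshape(a: Tensor, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)
    if not a.requires_grad:
        return Tensor(out_data)
    out = Tensor(out_data, True, (a,))
    out._backward = lambda g: a._accumulate(g.reshape(a.data.shape))
    return out


def mean(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out_data = np.asarray(a.data.mean())
    if not a.requires_grad:
        return Tensor(out_data)
    out = Tensor(out_data, True, (a,))
    inv = 1.0 / a.data.size
    out._backward = lambda g: a._accumulate(np.full_like(a.data, g * inv))
    return out


def absolute(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out_data = np.abs(a.data)
    if not a.requires_grad:
        return Tensor(out_data)
    out = Tensor(out_data, True, (a,))
    out._backward = lambda g: a._accumulate(g * np.sign(a.data))
    return out


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, slope * a.data)
    if not a.requires_grad:
        return Tensor(out_data)
    out = Tensor(out_data, True, (a,))
    out._backward = lambda g: a._accumulate(g * np.where(mask, 1.0, slope))
    return out


def relu(a: Tensor) -> Tensor:
    return leaky_relu(a, 0.0)


def sigmoid(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))
    if not a.requires_grad:
        return Tensor(out_data)
    out = Tensor(out_data, True, (a,))
    out._backward = lambda g: a._accumulate(g * out_data * (1.0 - out_data))
    return out


def tanh(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out_data = np.tanh(a.data)
    if not a.requires_grad:
        return Tensor(out_data)
    out = Tensor(out_data, True, (a,))
    out._backward = lambda g: a._accumulate(g * (1.0 - out_data**2))
    return out


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)
    if not a.requires_grad:
        return Tensor(out_data)
    out = Tensor(out_data, True, (a,))

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accumulate(out_data * (g - dot))

    out._backward = backward
    return out


def log(a: Tensor, eps: float = 0.0) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(a.data + eps)
    if not a.requires_grad:
        return Tensor(out_data)
    out = Tensor(out_data, True, (a,))
    out._backward = lambda g: a._accumulate(g / (a.data + eps))
    return out


def gather_rows(a: Tensor, index: np.ndarray) -> Tensor:
    """Select a[i, index[i]] for each row i of a 2-D tensor."""
    a = as_tensor(a)
    index = np.asarray(index, dtype=np.int64)
    rows = np.arange(a.data.shape[0])
    out_data = a.data[rows, index]
    if not a.requires_grad:
        return Tensor(out_data)
    out = Tensor(out_data, True, (a,))

    def backward(g):
        full = np.zeros_like(a.data)
        full[rows, index] = g
        a._accumulate(full)

    out._backward = backward
    return out


def instance_norm(a: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise each (batch, channel) plane over its spatial extent."""
    a = as_tensor(a)
    x = a.data
    mu = x.mean(axis=(-2, -1), keepdims=True)
    xc = x - mu
    var = (xc**2).mean(axis=(-2, -1), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    out_data = xc * inv
    if not a.requires_grad:
        return Tensor(out_data)
    out = Tensor(out_data, True, (a,))
    m = x.shape[-1] * x.shape[-2]

    def backward(g):
        # d/dx of (x - mu) / sqrt(var + eps)
        gs = g.sum(axis=(-2, -1), keepdims=True)
        gy = (g * out_data).sum(axis=(-2, -1), keepdims=True)
        a._accumulate(inv * (g - gs / m - out_data * gy / m))

    out._backward = backward
    return out


# ------------------------------------------------------------- convolutions
def _im2col(xp: np.ndarray, k: int, stride: int):
    """(B, C, Hp, Wp) -> (B, C*k*k, L) patch matrix, plus output geometry."""
    b, c, hp, wp = xp.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B, C, Ho, Wo, k, k)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(gcols: np.ndarray, xp_shape, k: int, stride: int, ho: int, wo: int):
    b, c, hp, wp = xp_shape
    g = np.zeros(xp_shape, dtype=gcols.dtype)
    gwin = gcols.reshape(b, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            g[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += gwin[
                :, :, i, j
            ]
    return g


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernel."""
    x, w = as_tensor(x), as_tensor(w)
    nb, c, _, _ = x.data.shape
    f, cin, k, _ = w.data.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cin}")
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    cols, ho, wo = _im2col(xp, k, stride)
    wmat = w.data.reshape(f, -1)
    out_data = np.matmul(wmat, cols).reshape(nb, f, ho, wo)
    if b is not None:
        out_data += b.data.reshape(1, f, 1, 1)
    parents = (x, w) + ((b,) if b is not None else ())
    if not _needs(*parents):
        return Tensor(out_data)
    out = Tensor(out_data, True, parents)

    def backward(g):
        gmat = g.reshape(nb, f, ho * wo)
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=(0, 2)))
        if w.requires_grad:
            gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(gw.reshape(w.data.shape))
        if x.requires_grad:
            gcols = np.matmul(wmat.T, gmat)
            gxp = _col2im(gcols, xp.shape, k, stride, ho, wo)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    out._backward = backward
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = x.data.repeat(2, axis=-2).repeat(2, axis=-1)
    if not x.requires_grad:
        return Tensor(out_data)
    out = Tensor(out_data, True, (x,))

    def backward(g):
        b, c, h2, w2 = g.shape
        x._accumulate(g.reshape(b, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    out._backward = backward
    return out


def sqrt(a: Tensor, eps: float = 0.0) -> Tensor:
    a = as_tensor(a)
    out_data = np.sqrt(a.data + eps)
    if not _needs(a):
        return Tensor(out_data)
    out = Tensor(out_data, True, (a,))
    out._backward = lambda g: a._accumulate(g * 0.5 / np.maximum(out_data, 1e-12))
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    if not _needs(*tensors):
        return Tensor(out_data)
    out = Tensor(out_data, True, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = backward
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = x.data.mean(axis=(-2, -1))
    if not x.requires_grad:
        return Tensor(out_data)
    out = Tensor(out_data, True, (x,))
    b, c, h, w = x.data.shape

    def backward(g):
        x._accumulate(np.broadcast_to(g[..., None, None] / (h * w), x.data.shape).copy())

    out._backward = backward
    return out


def linear(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """x (B, D) @ w.T (D, F) + b."""
    out = matmul(x, transpose(w))
    if b is not None:
        out = add(out, b)
    return out


def transpose(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.T
    if not a.requires_grad:
        return Tensor(out_data)
    out = Tensor(out_data, True, (a,))
    out._backward = lambda g: a._accumulate(g.T)
    return out
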