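"""Minimal reverse-mode automatic differentiation over numpy arrays.

The trainable parts of this package -- the dilated unary network, the
pairwise similarity network, the compatibility table, and the recurrent
mean-field layer -- are small enough that a tape-based autodiff engine
over dense float64 numpy arrays is both fast and easy to verify.  The
engine supports exactly the primitives those models need: elementwise
arithmetic with broadcasting, channelwise (1x1) and dilated 3x3
convolutions in HWC layout, spatial shifts with zero padding, sigmoid /
relu / exp / log nonlinearities, a softmax over the trailing axis,
concatenation, clamping and reductions.

Gradient correctness of every primitive is checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "parameter",
    "add",
    "sub",
    "mul",
    "neg",
    "scale",
    "tsum",
    "conv1x1",
    "conv3x3",
    "shift2d",
    "shift_array",
    "sigmoid",
    "relu",
    "exp",
    "log",
    "clamp_min",
    "softmax",
    "channel",
    "transpose2d",
    "concat",
    "SGD",
]


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # Operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return neg(self)

    def sum(self):
        return tsum(self)

    def detach(self):
        return Tensor(self.data.copy())

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        """Backpropagate from a scalar tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: the tape can exceed recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, _parents=(a, b))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = _bw
    return out


def sub(a, b) -> Tensor:
    return add(a, neg(as_tensor(b)))


def neg(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(-a.data, _parents=(a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(-g)

    out._backward = _bw
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, _parents=(a, b))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = _bw
    return out


def scale(a, k: float) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data * k, _parents=(a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g * k)

    out._backward = _bw
    return out


def tsum(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.sum(), _parents=(a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(np.full_like(a.data, float(g)))

    out._backward = _bw
    return out


def conv1x1(x, w, b=None) -> Tensor:
    """Channelwise linear map: (H, W, Cin) x (Cin, Cout) -> (H, W, Cout)."""
    x, w = as_tensor(x), as_tensor(w)
    parents = [x, w]
    y = np.tensordot(x.data, w.data, axes=([x.data.ndim - 1], [0]))
    if b is not None:
        b = as_tensor(b)
        parents.append(b)
        y = y + b.data
    out = Tensor(y, _parents=tuple(parents))

    def _bw(g):
        if x.requires_grad:
            x._accumulate(np.tensordot(g, w.data, axes=([g.ndim - 1], [1])))
        if w.requires_grad:
            axes = list(range(g.ndim - 1))
            w._accumulate(np.tensordot(x.data, g, axes=(axes, axes)))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=tuple(range(g.ndim - 1))))

    out._backward = _bw
    return out


def shift_array(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """out[y, x] = a[y + dy, x + dx], zero outside the image."""
    H, W = a.shape[0], a.shape[1]
    out = np.zeros_like(a)
    y0, y1 = max(0, -dy), min(H, H - dy)
    x0, x1 = max(0, -dx), min(W, W - dx)
    if y0 < y1 and x0 < x1:
        out[y0:y1, x0:x1] = a[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
    return out


def shift2d(x, dy: int, dx: int) -> Tensor:
    x = as_tensor(x)
    out = Tensor(shift_array(x.data, dy, dx), _parents=(x,))

    def _bw(g):
        if x.requires_grad:
            x._accumulate(shift_array(g, -dy, -dx))

    out._backward = _bw
    return out


def conv3x3(x, w, b=None, dilation: int = 1) -> Tensor:
    """Dilated 3x3 convolution, HWC layout, zero padded to preserve H x W.

    `w` has shape (3, 3, Cin, Cout); tap (a, c) is applied to the pixel at
    offset (dilation*(a-1), dilation*(c-1)).
    """
    x, w = as_tensor(x), as_tensor(w)
    if w.data.shape[:2] != (3, 3):
        raise ValueError("conv3x3 expects a (3, 3, Cin, Cout) kernel")
    d = int(dilation)
    parents = [x, w]
    H, W, _ = x.data.shape
    y = np.zeros((H, W, w.data.shape[3]))
    for a in range(3):
        for c in range(3):
            xs = shift_array(x.data, d * (a - 1), d * (c - 1))
            y += np.tensordot(xs, w.data[a, c], axes=([2], [0]))
    if b is not None:
        b = as_tensor(b)
        parents.append(b)
        y = y + b.data
    out = Tensor(y, _parents=tuple(parents))

    def _bw(g):
        for a in range(3):
            for c in range(3):
                dy, dx = d * (a - 1), d * (c - 1)
                if x.requires_grad:
                    x._accumulate(
                        shift_array(
                            np.tensordot(g, w.data[a, c], axes=([2], [1])), -dy, -dx
                        )
                    )
                if w.requires_grad:
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[a, c] += np.tensordot(
                        shift_array(x.data, dy, dx), g, axes=([0, 1], [0, 1])
                    )
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1)))

    out._backward = _bw
    return out


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, _parents=(a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g * s * (1.0 - s))

    out._backward = _bw
    return out


def relu(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.maximum(a.data, 0.0), _parents=(a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g * (a.data > 0))

    out._backward = _bw
    return out


def exp(a) -> Tensor:
    a = as_tensor(a)
    e = np.exp(a.data)
    out = Tensor(e, _parents=(a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g * e)

    out._backward = _bw
    return out


def log(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.log(a.data), _parents=(a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    out._backward = _bw
    return out


def clamp_min(a, lo: float) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.maximum(a.data, lo), _parents=(a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g * (a.data > lo))

    out._backward = _bw
    return out


def softmax(a) -> Tensor:
    """Softmax over the trailing axis."""
    a = as_tensor(a)
    z = a.data - a.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(s, _parents=(a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(s * (g - (g * s).sum(axis=-1, keepdims=True)))

    out._backward = _bw
    return out


def channel(a, k: int) -> Tensor:
    """Select channel k of the trailing axis, keeping it as size 1."""
    a = as_tensor(a)
    out = Tensor(a.data[..., k : k + 1], _parents=(a,))

    def _bw(g):
        if a.requires_grad:
            ga = np.zeros_like(a.data)
            ga[..., k : k + 1] = g
            a._accumulate(ga)

    out._backward = _bw
    return out


def transpose2d(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.T, _parents=(a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g.T)

    out._backward = _bw
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors)
    )
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = _bw
    return out


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr: float = 1e-3, momentum: float = 0.9):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v
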