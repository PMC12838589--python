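"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine in float64, sized for desk-scale volumetric
models: elementwise arithmetic, matmul, reductions, reshaping, padding,
slicing, concatenation, and 3D convolution / transposed convolution via
im2col.  Gradients are exact (no stochastic estimators), which lets the
test-suite compare every analytic gradient against central finite
differences.

Only `Tensor` and the free functions defined here are public API; layers
live in :mod:`damlm.model`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concatenate",
    "conv3d",
    "conv_transpose3d",
    "no_grad_context",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._backward = _backward
        self.grad: np.ndarray | None = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        if self.data.size != 1:
            raise ValueError("item() requires a single-element tensor")
        return float(self.data.reshape(()))

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion limit
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    # -------------------------------------------------------------- unary ops
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * 0.5 / out.data)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (self.data > 0))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * s * (1 - s))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1 - t * t))
        return out

    def prelu(self, alpha: "Tensor"):
        """PReLU with a broadcastable slope `alpha` for the negative part."""
        pos = self.data > 0
        out = Tensor(np.where(pos, self.data, alpha.data * self.data), _parents=(self, alpha))

        def bw(g):
            if self.requires_grad:
                self._accum(g * np.where(pos, 1.0, alpha.data))
            if alpha.requires_grad:
                alpha._accum(_unbroadcast(g * np.where(pos, 0.0, self.data), alpha.shape))

        out._backward = bw
        return out

    def clip_min(self, lo: float):
        """max(x, lo) with a straight-through gradient where x > lo."""
        out = Tensor(np.maximum(self.data, lo), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (self.data > lo))
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # --------------------------------------------------------------- reshapes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.shape
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(src))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bw
        return out

    # --------------------------------------------------------------- softmax
    def softmax(self, axis=-1):
        """Numerically stable softmax (max-subtraction; shift-invariant)."""
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis=-1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bw
    return out


# ------------------------------------------------------------------ conv ops
def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(B,C,X,Y,Z) -> (B, C*k^3, L) patch matrix at the strided lattice.

    Built by an offset loop over the k^3 kernel taps (each tap is one
    cheap strided copy), which is much faster than transposing an 8-D
    sliding-window view.
    """
    b, c = x.shape[:2]
    if pad:
        xp = np.zeros((b, c) + tuple(s + 2 * pad for s in x.shape[2:]))
        xp[:, :, pad:-pad, pad:-pad, pad:-pad] = x
        x = xp
    ox, oy, oz = ((s - k) // stride + 1 for s in x.shape[2:])
    L = ox * oy * oz
    # decompose into stride^3 contiguous subgrids so every tap slice below
    # is a cheap contiguous copy (big win for strided convolutions)
    s = stride
    subs = {(p, q, r): np.ascontiguousarray(x[:, :, p::s, q::s, r::s])
            for p in range(s) for q in range(s) for r in range(s)}
    cols = np.empty((b, c, k**3, L))
    t = 0
    for i in range(k):
        for j in range(k):
            for l in range(k):
                sub = subs[(i % s, j % s, l % s)]
                di, dj, dl = i // s, j // s, l // s
                cols[:, :, t, :] = sub[:, :, di:di + ox, dj:dj + oy,
                                       dl:dl + oz].reshape(b, c, L)
                t += 1
    return cols.reshape(b, c * k**3, L), (ox, oy, oz)


def _col2im(cols: np.ndarray, xshape, k: int, stride: int, pad: int, oshape) -> np.ndarray:
    """Adjoint of `_im2col`: scatter-add a (B, C*k^3, L) matrix back."""
    b, c, X, Y, Z = xshape
    ox, oy, oz = oshape
    s = stride
    pshape = tuple(n + 2 * pad for n in (X, Y, Z))
    taps = cols.reshape(b, c, k**3, ox, oy, oz)
    # accumulate per stride-parity subgrid (contiguous adds), interleave once
    accs = {(p, q, r): np.zeros((b, c) + tuple(-(-(n - u) // s)
                                               for n, u in zip(pshape, (p, q, r))))
            for p in range(s) for q in range(s) for r in range(s)}
    t = 0
    for i in range(k):
        for j in range(k):
            for l in range(k):
                acc = accs[(i % s, j % s, l % s)]
                di, dj, dl = i // s, j // s, l // s
                acc[:, :, di:di + ox, dj:dj + oy, dl:dl + oz] += taps[:, :, t]
                t += 1
    out = np.zeros((b, c) + pshape)
    for (p, q, r), acc in accs.items():
        out[:, :, p::s, q::s, r::s] = acc
    if pad:
        out = out[:, :, pad:-pad, pad:-pad, pad:-pad]
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int | None = None) -> Tensor:
    """3D convolution. x: (B,Ci,X,Y,Z); w: (Co,Ci,k,k,k); 'same' pad by default."""
    co, ci, k, _, _ = w.shape
    if pad is None:
        pad = k // 2
    cols, oshape = _im2col(x.data, k, stride, pad)  # (B, Ci*k^3, L)
    wmat = w.data.reshape(co, ci * k**3)
    out_data = np.matmul(wmat, cols)  # (B, Co, L)
    bsz = x.shape[0]
    out_data = out_data.reshape(bsz, co, *oshape)
    if b is not None:
        out_data = out_data + b.data.reshape(1, co, 1, 1, 1)
    out = Tensor(out_data, _parents=(x, w) + ((b,) if b is not None else ()))

    def bw(g):
        g_flat = g.reshape(bsz, co, -1)  # (B, Co, L)
        if w.requires_grad:
            gw = np.einsum("bol,bkl->ok", g_flat, cols)
            w._accum(gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(g_flat.sum(axis=(0, 2)))
        if x.requires_grad:
            gc = np.matmul(wmat.T, g_flat)  # (B, Ci*k^3, L)
            x._accum(_col2im(gc, x.shape, k, stride, pad, oshape))

    out._backward = bw
    return out


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2) -> Tensor:
    """Transposed 3D convolution (adjoint of a zero-pad conv).

    x: (B,Ci,X,Y,Z); w: (Ci,Co,k,k,k); output spatial size (X-1)*stride + k.
    With k == stride this is exact non-overlapping upsampling.
    """
    ci, co, k, _, _ = w.shape
    bsz, _, X, Y, Z = x.shape
    oshape = tuple((n - 1) * stride + k for n in (X, Y, Z))
    wmat = w.data.reshape(ci, co * k**3)
    x_flat = x.data.reshape(bsz, ci, -1)  # (B, Ci, L)
    cols = np.matmul(wmat.T, x_flat)  # (B, Co*k^3, L)
    out_data = _col2im(cols, (bsz, co) + oshape, k, stride, 0, (X, Y, Z))
    if b is not None:
        out_data = out_data + b.data.reshape(1, co, 1, 1, 1)
    out = Tensor(out_data, _parents=(x, w) + ((b,) if b is not None else ()))

    def bw(g):
        g_cols, _ = _im2col(g, k, stride, 0)  # (B, Co*k^3, L)
        if x.requires_grad:
            x._accum(np.matmul(wmat, g_cols).reshape(x.shape))
        if w.requires_grad:
            gw = np.einsum("bil,bkl->ik", x_flat, g_cols)
            w._accum(gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))

    out._backward = bw
    return out


class no_grad_context:
    """Marker context: wraps forward passes whose graph is discarded anyway.

    The engine builds graphs lazily per-Tensor, so "no grad" simply means
    feeding plain (requires_grad=False) tensors; this context exists for
    readability at call sites.
    """

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False
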