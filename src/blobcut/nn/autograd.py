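"""A compact reverse-mode automatic differentiation engine on numpy arrays.

Just enough machinery for the volumetric translation networks in this
package: broadcasting arithmetic, matmul, pointwise nonlinearities,
reductions, shape ops, 3D convolution (im2col), zero-stuffing upsampling
(fractional-strided convolution), and row gathering for patch sampling.
Tensors are float32; gradients accumulate in ``.grad``.  ``backward()``
replays the tape in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "conv3d", "zero_stuff3d", "take_rows", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node of the computation graph wrapping a float32 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # ---- bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = grad.astype(np.float32, copy=False)
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
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
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ---- arithmetic --------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

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
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * as_tensor(other).pow(-1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        """Elementwise power with a constant exponent."""
        out = Tensor(self.data**exponent, _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    # ---- pointwise nonlinearities ------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bwd
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out.data**2))

        out._backward = bwd
        return out

    def sigmoid(self):
        x = self.data
        sig = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                       np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = Tensor(sig, _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out.data * (1.0 - out.data))

        out._backward = bwd
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        out._backward = bwd
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * np.where(self.data > 0, 1.0, slope))

        out._backward = bwd
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * np.sign(self.data))

        out._backward = bwd
        return out

    # ---- reductions and shape ops ------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.shape[a] for a in axis]))
        else:
            n = self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = bwd
        return out

    def transpose(self, axes):
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = bwd
        return out

    def logsumexp(self, axis: int, keepdims: bool = False):
        """Numerically stable log-sum-exp along one axis."""
        m = self.data.max(axis=axis, keepdims=True)  # constant shift
        shifted = self - Tensor(m)
        out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
        if not keepdims:
            out = out.reshape(tuple(s for i, s in enumerate(out.shape) if i != axis))
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def take_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows of a 2D tensor; backward scatter-adds."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(x.data[idx], _prev=(x,))

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, idx, g)
            x._accumulate(gx)

    out._backward = bwd
    return out


def _pad3(x: np.ndarray, pad: int, mode: str) -> np.ndarray:
    if pad == 0:
        return x
    spec = ((0, 0), (pad, pad), (pad, pad), (pad, pad))
    return np.pad(x, spec, mode="edge" if mode == "replicate" else "constant")


def _fold_pad_grad(gp: np.ndarray, pad: int, mode: str) -> np.ndarray:
    """Backward of _pad3: fold border gradients onto edges (replicate) or drop."""
    if pad == 0:
        return gp
    if mode != "replicate":
        return gp[:, pad:-pad, pad:-pad, pad:-pad]
    g = gp
    for ax in (1, 2, 3):
        sl_lo = [slice(None)] * 4
        sl_lo[ax] = slice(0, pad)
        sl_edge_lo = [slice(None)] * 4
        sl_edge_lo[ax] = slice(pad, pad + 1)
        sl_hi = [slice(None)] * 4
        sl_hi[ax] = slice(g.shape[ax] - pad, g.shape[ax])
        sl_edge_hi = [slice(None)] * 4
        sl_edge_hi[ax] = slice(g.shape[ax] - pad - 1, g.shape[ax] - pad)
        g = g.copy()
        g[tuple(sl_edge_lo)] += g[tuple(sl_lo)].sum(axis=ax, keepdims=True)
        g[tuple(sl_edge_hi)] += g[tuple(sl_hi)].sum(axis=ax, keepdims=True)
        keep = [slice(None)] * 4
        keep[ax] = slice(pad, g.shape[ax] - pad)
        g = g[tuple(keep)]
    return g


def conv3d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    pad: int = 0,
    pad_mode: str = "replicate",
) -> Tensor:
    """3D convolution (cross-correlation) accumulated over kernel offsets.

    ``x``: (Cin, D, H, W); ``w``: (Cout, Cin, k, k, k); ``b``: (Cout,).
    Returns (Cout, D', H', W').  One (Cout, Cin) matmul per kernel offset
    keeps memory at O(Cout * output voxels) instead of a full im2col buffer.
    """
    cin, k = w.shape[1], w.shape[2]
    cout = w.shape[0]
    assert x.shape[0] == cin, f"channel mismatch: {x.shape[0]} vs {cin}"
    xp = _pad3(x.data, pad, pad_mode)
    od = (xp.shape[1] - k) // stride + 1
    oh = (xp.shape[2] - k) // stride + 1
    ow = (xp.shape[3] - k) // stride + 1
    n = od * oh * ow

    def shifted(a, bb, c):
        """View of the padded input aligned with kernel offset (a, bb, c)."""
        return xp[
            :,
            a : a + stride * od : stride,
            bb : bb + stride * oh : stride,
            c : c + stride * ow : stride,
        ].reshape(cin, n)

    out_flat = np.zeros((cout, n), dtype=np.float32)
    for a in range(k):
        for bb in range(k):
            for c in range(k):
                out_flat += w.data[:, :, a, bb, c] @ shifted(a, bb, c)
    if b is not None:
        out_flat += b.data[:, None]
    out = Tensor(out_flat.reshape(cout, od, oh, ow), _prev=(x, w) if b is None else (x, w, b))

    def bwd(g):
        g2 = g.reshape(cout, n)
        if b is not None and b.requires_grad:
            b._accumulate(g2.sum(axis=1))
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for a in range(k):
                for bb in range(k):
                    for c in range(k):
                        gw[:, :, a, bb, c] = g2 @ shifted(a, bb, c).T
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for a in range(k):
                for bb in range(k):
                    for c in range(k):
                        gxp[
                            :,
                            a : a + stride * od : stride,
                            bb : bb + stride * oh : stride,
                            c : c + stride * ow : stride,
                        ] += (w.data[:, :, a, bb, c].T @ g2).reshape(cin, od, oh, ow)
            x._accumulate(_fold_pad_grad(gxp, pad, pad_mode))

    out._backward = bwd
    return out


def zero_stuff3d(x: Tensor, factor: int = 2) -> Tensor:
    """Insert zeros between voxels (stride-``factor`` transposed upsampling).

    Followed by an ordinary convolution this realizes a fractional-strided
    (transposed) convolution.
    """
    c, d, h, w = x.shape
    data = np.zeros((c, d * factor, h * factor, w * factor), dtype=np.float32)
    data[:, ::factor, ::factor, ::factor] = x.data
    out = Tensor(data, _prev=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g[:, ::factor, ::factor, ::factor])

    out._backward = bwd
    return out
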