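"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients.  Only the operations needed by the transformer and
U-Net models in this package are implemented, all with full broadcasting
support.  float32 is the working dtype throughout.
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable tape recording inside the block (inference / sampling)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_grad_fns")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._grad_fns: tuple = ()

    # -- construction of graph nodes -------------------------------------
    @staticmethod
    def _node(data, parents, grad_fns):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._grad_fns = tuple(grad_fns)
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        return Tensor._node(
            self.data + other.data,
            (self, other),
            (lambda g: _unbroadcast(g, self.data.shape),
             lambda g: _unbroadcast(g, other.data.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._node(-self.data, (self,), (lambda g: -g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        return Tensor._node(
            self.data * other.data,
            (self, other),
            (lambda g: _unbroadcast(g * other.data, self.data.shape),
             lambda g: _unbroadcast(g * self.data, other.data.shape)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        d = self.data
        return Tensor._node(
            d ** p, (self,),
            (lambda g: g * p * d ** (p - 1.0),),
        )

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data

        def ga(g):
            if b.ndim == 1:
                out = np.outer(g, b) if a.ndim > 1 else g * b
            else:
                out = g @ b.swapaxes(-1, -2)
            return _unbroadcast(out, a.shape)

        def gb(g):
            if a.ndim == 1:
                out = np.outer(a, g) if b.ndim > 1 else a * g
            else:
                out = a.swapaxes(-1, -2) @ g
            return _unbroadcast(out, b.shape)

        return Tensor._node(a @ b, (self, other), (ga, gb))

    # -- reductions / shaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        d = self.data

        def g_fn(g):
            if axis is None:
                return np.broadcast_to(g, d.shape).copy()
            g2 = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(g2, d.shape).copy()

        return Tensor._node(d.sum(axis=axis, keepdims=keepdims), (self,), (g_fn,))

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else (
            np.prod([self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._node(
            self.data.reshape(shape), (self,),
            (lambda g: g.reshape(old),),
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._node(
            self.data.transpose(axes), (self,),
            (lambda g: g.transpose(inv),),
        )

    def swapaxes(self, a: int, b: int):
        return Tensor._node(
            self.data.swapaxes(a, b), (self,),
            (lambda g: g.swapaxes(a, b),),
        )

    def __getitem__(self, idx):
        d = self.data

        def g_fn(g):
            out = np.zeros_like(d)
            np.add.at(out, idx, g)
            return out

        return Tensor._node(d[idx], (self,), (g_fn,))

    # -- elementwise nonlinearities ----------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return Tensor._node(out, (self,), (lambda g: g * out,))

    def log(self):
        d = self.data
        return Tensor._node(np.log(d), (self,), (lambda g: g / d,))

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._node(out, (self,), (lambda g: g * (1.0 - out * out),))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._node(out, (self,), (lambda g: g * out * (1.0 - out),))

    def relu(self):
        d = self.data
        return Tensor._node(np.maximum(d, 0.0), (self,), (lambda g: g * (d > 0),))

    def gelu(self):
        """GELU via the standard tanh approximation (fast and within ~1e-3
        of the erf form)."""
        d = self.data
        c = np.float32(math.sqrt(2.0 / math.pi))
        a = np.float32(0.044715)
        u = c * (d + a * d * d * d)
        th = np.tanh(u)
        half = np.float32(0.5)
        out = half * d * (1.0 + th)
        du = c * (1.0 + 3.0 * a * d * d)
        deriv = half * (1.0 + th) + half * d * (1.0 - th * th) * du
        return Tensor._node(out, (self,), (lambda g: g * deriv,))

    def softmax(self, axis: int = -1):
        d = self.data
        e = np.exp(d - d.max(axis=axis, keepdims=True))
        s = e / e.sum(axis=axis, keepdims=True)

        def g_fn(g):
            return s * (g - (g * s).sum(axis=axis, keepdims=True))

        return Tensor._node(s, (self,), (g_fn,))

    # -- backward ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, fn in zip(node._parents, node._grad_fns):
                if not parent.requires_grad:
                    continue
                contrib = np.asarray(fn(node.grad), dtype=np.float32)
                if parent.grad is None:
                    parent.grad = contrib.copy() if contrib.base is not None else contrib
                else:
                    parent.grad = parent.grad + contrib
            if node._parents:  # free intermediate grads
                node.grad = None


# -- free functions ---------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def make_fn(i):
        def g_fn(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            return g[tuple(sl)]
        return g_fn

    return Tensor._node(
        np.concatenate(datas, axis=axis), tuple(tensors),
        tuple(make_fn(i) for i in range(len(tensors))),
    )


def stack_rows(t: Tensor, index: np.ndarray, axis: int = 1) -> Tensor:
    """Batched row gather: ``t[b, index[b], :]`` for a (B, N, D) tensor."""
    B = t.shape[0]
    bidx = np.arange(B)[:, None]
    return t[bidx, index]


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """LayerNorm over the trailing axis (fused primitive)."""
    d = x.data
    mu = d.mean(axis=-1, keepdims=True)
    xc = d - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + np.float32(eps))
    y = xc * inv                                     # normalized
    gd, bd = gamma.data, beta.data

    def gx(g):
        gy = g * gd
        return inv * (gy - gy.mean(axis=-1, keepdims=True)
                      - y * (gy * y).mean(axis=-1, keepdims=True))

    def ggamma(g):
        return (g * y).reshape(-1, d.shape[-1]).sum(axis=0)

    def gbeta(g):
        return g.reshape(-1, d.shape[-1]).sum(axis=0)

    return Tensor._node(y * gd + bd, (x, gamma, beta), (gx, ggamma, gbeta))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernel/stride/padding.

    Implemented as a fused primitive (im2col forward, col2im backward) so the
    tape stays short for image-sized inputs.
    """
    xd, wd = x.data, w.data
    B, C, H, W = xd.shape
    O, Cw, K, _ = wd.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, kernel {Cw}")
    if padding:
        xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = xd
    Hp, Wp = xp.shape[2], xp.shape[3]
    OH = (Hp - K) // stride + 1
    OW = (Wp - K) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (K, K), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]            # B,C,OH,OW,K,K
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * OH * OW, C * K * K)
    wmat = wd.reshape(O, C * K * K)
    out = cols @ wmat.T
    if b is not None:
        out = out + b.data
    out = out.reshape(B, OH, OW, O).transpose(0, 3, 1, 2)

    def gx(g):
        gcols = g.transpose(0, 2, 3, 1).reshape(B * OH * OW, O) @ wmat
        gcols = gcols.reshape(B, OH, OW, C, K, K)
        gxp = np.zeros((B, C, Hp, Wp), dtype=np.float32)
        for i in range(K):
            for j in range(K):
                gxp[:, :, i:i + OH * stride:stride, j:j + OW * stride:stride] += (
                    gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2))
        if padding:
            return gxp[:, :, padding:-padding, padding:-padding]
        return gxp

    def gw(g):
        gout = g.transpose(0, 2, 3, 1).reshape(B * OH * OW, O)
        return (gout.T @ cols).reshape(O, C, K, K)

    parents = [x, w]
    fns = [gx, gw]
    if b is not None:
        parents.append(b)
        fns.append(lambda g: g.transpose(0, 2, 3, 1).reshape(-1, O).sum(axis=0))
    return Tensor._node(out, tuple(parents), tuple(fns))


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling (NCHW)."""
    d = x.data
    out = d.repeat(2, axis=2).repeat(2, axis=3)
    B, C, H, W = d.shape

    def g_fn(g):
        return g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5))

    return Tensor._node(out, (x,), (g_fn,))
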