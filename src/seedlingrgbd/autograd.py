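"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tensor engine providing exactly the operations the growth-stage
classifiers need: broadcast arithmetic, (batched) matmul, 3x3 same-padding
convolution, 2x2 max-pooling, ReLU/sigmoid/tanh, softmax, layer
normalisation, dropout and a fused softmax cross-entropy loss.  Gradients
are accumulated by topological-order backpropagation.  All operations are
deterministic; stochastic ones (dropout) draw from an explicit
``numpy.random.Generator``.

The engine favours clarity over generality: shapes are whatever NumPy
broadcasting allows, float64 throughout, CPU only.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "layer_norm", "softmax_cross_entropy",
           "conv2d_3x3", "maxpool2x2", "dropout"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph ------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__
    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- shape ------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(src))

        out._backward = bwd
        return out

    def transpose(self, axes) -> "Tensor":
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.mean(axis=axis, keepdims=keepdims), parents=(self,))
        n = self.data.size / out.data.size

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape) / n)

        out._backward = bwd
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    # -- nonlinearities ---------------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out._backward = bwd
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * s * (1 - s))

        out._backward = bwd
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1 - t * t))

        out._backward = bwd
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    out._backward = bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accum(s * (g - dot))

    out._backward = bwd
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise over the last axis, then scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data, parents=(x, gamma, beta))
    d = x.data.shape[-1]

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            gx = g * gamma.data
            t1 = gx - gx.mean(axis=-1, keepdims=True)
            t2 = xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv * (t1 - t2))

    out._backward = bwd
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of (N, K) logits against integer labels (N,)."""
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = logits.data.shape[0]
    loss = -logp[np.arange(n), labels].mean()
    out = Tensor(loss, parents=(logits,))
    probs = np.exp(logp)

    def bwd(g):
        if logits.requires_grad:
            d = probs.copy()
            d[np.arange(n), labels] -= 1.0
            logits._accum(g * d / n)

    out._backward = bwd
    return out


def conv2d_3x3(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """3x3 convolution, stride 1, same (zero) padding.

    x: (N, C, H, W); w: (F, C, 3, 3); b: (F,).  Implemented as nine
    shifted tensor contractions, which keeps both passes as large matrix
    products.
    """
    xd, wd = x.data, w.data
    n, c, h, ww = xd.shape
    f = wd.shape[0]
    xp = np.pad(xd, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out_d = np.zeros((n, f, h, ww))
    for dy in range(3):
        for dx in range(3):
            patch = xp[:, :, dy : dy + h, dx : dx + ww]
            out_d += np.einsum("fc,nchw->nfhw", wd[:, :, dy, dx], patch, optimize=True)
    out_d += b.data[None, :, None, None]
    out = Tensor(out_d, parents=(x, w, b))

    def bwd(g):
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad or x.requires_grad:
            gxp = np.zeros_like(xp) if x.requires_grad else None
            for dy in range(3):
                for dx in range(3):
                    patch = xp[:, :, dy : dy + h, dx : dx + ww]
                    if w.requires_grad:
                        gw = np.einsum("nfhw,nchw->fc", g, patch, optimize=True)
                        if w.grad is None:
                            w.grad = np.zeros_like(wd)
                        w.grad[:, :, dy, dx] += gw
                    if x.requires_grad:
                        gxp[:, :, dy : dy + h, dx : dx + ww] += np.einsum(
                            "fc,nfhw->nchw", wd[:, :, dy, dx], g, optimize=True)
            if x.requires_grad:
                x._accum(gxp[:, :, 1 : 1 + h, 1 : 1 + ww])

    out._backward = bwd
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max-pooling with stride 2; odd trailing rows/columns are dropped."""
    xd = x.data
    n, c, h, w = xd.shape
    h2, w2 = h // 2, w // 2
    xc = xd[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
    xr = xc.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
    arg = xr.argmax(axis=-1)
    out = Tensor(np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0],
                 parents=(x,))

    def bwd(g):
        if not x.requires_grad:
            return
        gr = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(gr, arg[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(xd)
        gx[:, :, : 2 * h2, : 2 * w2] = (
            gr.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, 2 * h2, 2 * w2))
        x._accum(gx)

    out._backward = bwd
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p) / (1.0 - p)
    out = Tensor(x.data * keep, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * keep)

    out._backward = bwd
    return out
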