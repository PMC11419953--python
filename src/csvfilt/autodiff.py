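"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the primitives the classifier and the self-supervised
loss need: broadcasting arithmetic, matmul, 2-D convolution (im2col),
ReLU/sigmoid/exp/log/sqrt, reductions, reshape/transpose and a fused
softmax cross-entropy.  Gradients are accumulated on a tape and released
by :meth:`Tensor.backward`; correctness is pinned down by numerical
gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64 if np.asarray(data).dtype == np.float64 else np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        out = _node(self.data + other.data, (self, other))

        def back(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        out = _node(self.data * other.data, (self, other))

        def back(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        return self * other.pow(-1.0)

    def pow(self, exponent: float):
        out = _node(self.data ** exponent, (self,))
        out._backward = lambda g: self._accumulate(g * exponent * self.data ** (exponent - 1))
        return out

    def sqrt(self):
        return self.pow(0.5)

    def matmul(self, other: "Tensor"):
        out = _node(self.data @ other.data, (self, other))

        def back(g):
            if self.requires_grad or self._parents:
                self._accumulate(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad or other._parents:
                other._accumulate(self.data.swapaxes(-1, -2) @ g)

        out._backward = back
        return out

    __matmul__ = matmul

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = _node(self.data * mask, (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(s, (self,))
        out._backward = lambda g: self._accumulate(g * s * (1 - s))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = _node(e, (self,))
        out._backward = lambda g: self._accumulate(g * e)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def back(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = _node(self.data.transpose(*axes), (self,))
        inv = np.argsort(axes)
        out._backward = lambda g: self._accumulate(g.transpose(*inv))
        return out


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor.__new__(Tensor)
    out.data = data
    out.grad = None
    out.requires_grad = False
    out._parents = tuple(p for p in parents if p.requires_grad or p._parents)
    out._backward = None
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution: x (N,C,H,W), w (F,C,kh,kw), b (F,)."""
    n, c, h, wd = x.data.shape
    f, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    windows = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = windows.shape[2], windows.shape[3]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
    wmat = w.data.reshape(f, -1)
    out_data = (cols @ wmat.T + b.data).transpose(0, 2, 1).reshape(n, f, ho, wo)
    out = _node(np.ascontiguousarray(out_data), (x, w, b))

    def back(g):
        gmat = g.reshape(n, f, ho * wo).transpose(0, 2, 1)  # (N, L, F)
        if w.requires_grad or w._parents:
            dw = np.einsum("nlf,nlk->fk", gmat, cols, optimize=True)
            w._accumulate(dw.reshape(w.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(gmat.sum(axis=(0, 1)))
        if x.requires_grad or x._parents:
            dcols = gmat @ wmat  # (N, L, C*kh*kw)
            dcols = dcols.reshape(n, ho, wo, c, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    out._backward = back
    return out


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k average pooling (H, W must divide by k)."""
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {k}")
    return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain-array softmax (used at inference time)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over a batch; labels are integer class indices."""
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    loss = -logp[np.arange(n), labels].mean()
    out = _node(np.asarray(loss, dtype=logits.data.dtype), (logits,))

    def back(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits._accumulate(g * p / n)

    out._backward = back
    return out


class Adam:
    """Adam optimizer over a name -> Tensor parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 frozen: set[str] | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.frozen = frozen or set()
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        self._t += 1
        for name, p in self.params.items():
            if name in self.frozen or p.grad is None:
                continue
            m = self._m[name] = self.b1 * self._m[name] + (1 - self.b1) * p.grad
            v = self._v[name] = self.b2 * self._v[name] + (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self._t)
            vhat = v / (1 - self.b2 ** self._t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


__all__ = ["Tensor", "Adam", "conv2d", "avg_pool2d", "softmax", "softmax_cross_entropy"]
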