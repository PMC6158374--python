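"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A tape-based engine sized for the small networks in this package: dense
layers, valid-mode strided 2-D convolution, the squashing nonlinearity and
softmax needed for routing. Gradients are exact (no stop-gradients), so
every objective here can be checked against central finite differences.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "conv2d", "softmax", "squash", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.shape)

        return Tensor._from_op(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self.grad += -g

        return Tensor._from_op(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.shape)

        return Tensor._from_op(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def bw(g):
            if self.requires_grad:
                self.grad += g * exponent * self.data ** (exponent - 1)

        return Tensor._from_op(self.data ** exponent, (self,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)
        out = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.multiply.outer(g, other.data) if g.ndim else g * other.data
                else:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                self.grad += _unbroadcast(ga.reshape(self.shape) if ga.shape != self.shape and ga.size == self.data.size else ga, self.shape)
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.multiply.outer(self.data, g) if g.ndim else self.data * g
                else:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                other.grad += _unbroadcast(gb, other.shape)

        return Tensor._from_op(out, (self, other), bw)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            if self.requires_grad:
                self.grad += g.reshape(old)

        return Tensor._from_op(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self.grad += g.transpose(inv)

        return Tensor._from_op(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            if self.requires_grad:
                np.add.at(self.grad, idx, g)

        return Tensor._from_op(self.data[idx], (self,), bw)

    # -- reductions & elementwise ---------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += g
            elif keepdims:
                self.grad += g
            else:
                self.grad += np.expand_dims(g, axis)

        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self.grad += g * mask

        return Tensor._from_op(self.data * mask, (self,), bw)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            if self.requires_grad:
                self.grad += g * out * (1.0 - out)

        return Tensor._from_op(out, (self,), bw)

    def exp(self):
        out = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self.grad += g * out

        return Tensor._from_op(out, (self,), bw)

    def sqrt(self):
        return self ** 0.5

    def norm(self, axis=-1, keepdims=False, eps: float = 0.0):
        """Euclidean norm along `axis`; `eps` stabilises the gradient at 0."""
        return ((self * self).sum(axis=axis, keepdims=keepdims) + eps) ** 0.5


def concat(tensors, axis=0):
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t.grad += p

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bw
    )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        if x.requires_grad:
            dot = (g * out).sum(axis=axis, keepdims=True)
            x.grad += out * (g - dot)

    return Tensor._from_op(out, (x,), bw)


def squash(s: Tensor, axis: int = -1, eps: float = 1e-9) -> Tensor:
    """v = (|s|^2 / (1 + |s|^2)) * s / |s|, the capsule nonlinearity.

    Defined as 0 at s = 0 (the continuous limit); `eps` inside the norm
    keeps the gradient finite there.
    """
    n2 = (s * s).sum(axis=axis, keepdims=True)
    scale = (n2 + eps) ** -0.5 * (n2 * (1.0 + n2) ** -1.0)
    return s * scale


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """Valid-mode 2-D convolution (cross-correlation) via im2col.

    x: (B, C, H, W); w: (O, C, k, k); b: (O,). Output (B, O, Ho, Wo).
    """
    xd, wd = x.data, w.data
    B, C, H, W = xd.shape
    O, Cw, k, k2 = wd.shape
    if Cw != C or k != k2:
        raise ValueError(f"kernel {wd.shape} incompatible with input {xd.shape}")
    Ho = (H - k) // stride + 1
    Wo = (W - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xd, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]               # (B, C, Ho, Wo, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * k * k)
    wmat = wd.reshape(O, C * k * k)
    out = (cols @ wmat.T).reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data.reshape(1, O, 1, 1)

    def bw(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, O)
        if w.requires_grad:
            w.grad += (gmat.T @ cols).reshape(wd.shape)
        if b is not None and b.requires_grad:
            b.grad += g.sum(axis=(0, 2, 3))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(B, Ho, Wo, C, k, k)
            dx = np.zeros_like(xd)
            for ki in range(k):
                for kj in range(k):
                    dx[:, :, ki:ki + Ho * stride:stride, kj:kj + Wo * stride:stride] += \
                        dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
            x.grad += dx

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._from_op(out, parents, bw)


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
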