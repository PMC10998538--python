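"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the association-prediction model needs:
broadcasting add/mul, (batched) matmul, ReLU, max-pooling, concatenation,
row softmax, layer normalization and a numerically stable binary
cross-entropy with logits, plus an Adam optimizer.  Every op's gradient is
checked against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph mechanics ----------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- ops ----------------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        return Tensor(self.data + other.data, parents=(self, other), backward=bw)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    __radd__ = __add__
    __rmul__ = __mul__

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self.grad += _unbroadcast(ga, self.data.shape)
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other.grad += _unbroadcast(gb, other.data.shape)

        return Tensor(out_data, parents=(self, other), backward=bw)

    @property
    def T(self):
        def bw(g):
            if self.requires_grad:
                self.grad += np.swapaxes(g, -1, -2)

        return Tensor(np.swapaxes(self.data, -1, -2), parents=(self,), backward=bw)

    def __getitem__(self, key):
        def bw(g):
            if self.requires_grad:
                np.add.at(self.grad, key, g)

        return Tensor(self.data[key], parents=(self,), backward=bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self.grad += g * mask

        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def max(self, axis: int):
        """Max along ``axis``; ties send the gradient to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis),
                                      axis=axis).squeeze(axis)

        def bw(g):
            if self.requires_grad:
                gfull = np.zeros_like(self.data)
                np.put_along_axis(gfull, np.expand_dims(idx, axis),
                                  np.expand_dims(g, axis), axis=axis)
                self.grad += gfull

        return Tensor(out_data, parents=(self,), backward=bw)

    def sum(self):
        def bw(g):
            if self.requires_grad:
                self.grad += np.broadcast_to(g, self.data.shape)

        return Tensor(self.data.sum(), parents=(self,), backward=bw)

    def mean(self):
        return self.sum() * (1.0 / self.data.size)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self.grad += (g - dot) * y

        return Tensor(y, parents=(self,), backward=bw)

    def layer_norm(self, eps: float = 1e-5):
        """Normalize the last axis to zero mean, unit variance (no affine)."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc ** 2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = xc * inv

        def bw(g):
            if self.requires_grad:
                n = self.data.shape[-1]
                gm = g.mean(axis=-1, keepdims=True)
                gy = (g * y).mean(axis=-1, keepdims=True)
                self.grad += inv * (g - gm - y * gy)

        return Tensor(y, parents=(self,), backward=bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t.grad += p

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bw)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy of sigmoid(logits) against 0/1 targets."""
    x, t = logits.data, np.asarray(targets, dtype=float)
    loss = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))

    def bw(g):
        if logits.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-x))
            logits.grad += g * (sig - t) / x.size

    return Tensor(loss.mean(), parents=(logits,), backward=bw)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


class Parameter(Tensor):
    """Trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


class Adam:
    """Adam optimizer over a list of Parameters."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = np.zeros_like(p.data)
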