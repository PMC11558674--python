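"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for a small encoder-decoder transformer: broadcasted
add/mul, batched matmul, reshape/transpose, embedding gather, GELU,
softmax, layer normalization, dropout, and a fused masked cross-entropy.
Gradients are accumulated on a tape and released after ``backward``.
Correctness is pinned by numerical gradient checks in the test suite.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_diff = grad.ndim - len(shape)
    if ndim_diff > 0:
        grad = grad.sum(axis=tuple(range(ndim_diff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], tuple] | None = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for p, pg in zip(t._parents, t._backward(g)):
                    if not p.requires_grad or pg is None:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg
            else:  # leaf
                t.grad = g if t.grad is None else t.grad + g
        # leaves visited via topo with no _backward already handled above;
        # the root may itself be a leaf
        if self._backward is None and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=self.data.dtype)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def back(g):
            return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

        return Tensor._make(a.data + b.data, (a, b), back)

    def __mul__(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def back(g):
            return _unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)

        return Tensor._make(a.data * b.data, (a, b), back)

    def scale(self, c: float) -> "Tensor":
        a = self
        return Tensor._make(a.data * c, (a,), lambda g: (g * c,))

    def __neg__(self) -> "Tensor":
        return self.scale(-1.0)

    def __sub__(self, other: "Tensor") -> "Tensor":
        return self + (-other)

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def back(g):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            bshape_a = np.broadcast_shapes(a.shape[:-2], b.shape[:-2]) + a.shape[-2:]
            bshape_b = np.broadcast_shapes(a.shape[:-2], b.shape[:-2]) + b.shape[-2:]
            ga = _unbroadcast(ga.reshape(bshape_a) if ga.shape != bshape_a else ga, a.shape)
            gb = _unbroadcast(gb.reshape(bshape_b) if gb.shape != bshape_b else gb, b.shape)
            return ga, gb

        return Tensor._make(np.matmul(a.data, b.data), (a, b), back)

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        a = self
        old = a.shape
        return Tensor._make(a.data.reshape(*shape), (a,), lambda g: (g.reshape(old),))

    def transpose(self, *axes) -> "Tensor":
        a = self
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(*axes), (a,), lambda g: (g.transpose(*inv),)
        )

    def sum(self) -> "Tensor":
        a = self
        return Tensor._make(
            a.data.sum(), (a,), lambda g: (np.broadcast_to(g, a.shape),)
        )

    # -- nonlinearities ----------------------------------------------------

    def gelu(self) -> "Tensor":
        a = self
        x = a.data
        c = math.sqrt(2.0 / math.pi)
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out = 0.5 * x * (1.0 + t)

        def back(g):
            dinner = c * (1.0 + 3 * 0.044715 * x**2)
            d = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
            return (g * d,)

        return Tensor._make(out, (a,), back)

    def softmax(self) -> "Tensor":
        """Softmax over the last axis."""
        a = self
        z = a.data - a.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=-1, keepdims=True)

        def back(g):
            dot = (g * y).sum(axis=-1, keepdims=True)
            return (y * (g - dot),)

        return Tensor._make(y, (a,), back)

    def layer_norm(self, gain: "Tensor", bias: "Tensor", eps: float = 1e-5) -> "Tensor":
        """Normalize the last axis to zero mean / unit variance, then affine."""
        a = self
        x = a.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = xhat * gain.data + bias.data

        def back(g):
            n = x.shape[-1]
            gxhat = g * gain.data
            dx = (
                inv
                / n
                * (
                    n * gxhat
                    - gxhat.sum(axis=-1, keepdims=True)
                    - xhat * (gxhat * xhat).sum(axis=-1, keepdims=True)
                )
            )
            ggain = _unbroadcast(g * xhat, gain.shape)
            gbias = _unbroadcast(g, bias.shape)
            return dx, ggain, gbias

        return Tensor._make(out, (a, gain, bias), back)

    def dropout(self, p: float, rng: np.random.Generator) -> "Tensor":
        """Inverted dropout; identity when p == 0."""
        if p == 0.0:
            return self
        a = self
        keep = (rng.random(a.shape) >= p).astype(a.data.dtype) / (1.0 - p)
        return Tensor._make(a.data * keep, (a,), lambda g: (g * keep,))


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather ``table[ids]`` with scatter-add backward."""
    ids = np.asarray(ids)

    def back(g):
        gt = np.zeros_like(table.data)
        np.add.at(gt, ids.reshape(-1), g.reshape(-1, table.data.shape[-1]))
        return (gt,)

    return Tensor._make(table.data[ids], (table,), back)


def constant(data) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=False)


def masked_cross_entropy(logits: Tensor, targets: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean negative log-likelihood over positions where ``mask`` is true.

    ``logits``: [..., V]; ``targets``: integer array matching the leading
    shape; ``mask``: boolean/float array of the same leading shape. Returns
    a scalar tensor in nats per unmasked position.
    """
    a = logits
    x = a.data
    flat = x.reshape(-1, x.shape[-1])
    t = np.asarray(targets).reshape(-1)
    m = np.asarray(mask, dtype=x.dtype).reshape(-1)
    denom = m.sum()
    if denom <= 0:
        raise ValueError("cross-entropy mask selects no positions")
    z = flat - flat.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1))
    logp = z[np.arange(len(t)), t] - lse
    loss = -(m * logp).sum() / denom

    def back(g):
        soft = np.exp(z - lse[:, None])
        soft[np.arange(len(t)), t] -= 1.0
        dflat = soft * (m / denom)[:, None] * g
        return (dflat.reshape(x.shape),)

    return Tensor._make(np.asarray(loss, dtype=x.dtype), (a,), back)


class Adam:
    """Adaptive-moment gradient descent with global-norm clipping."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: float | None = 1.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        grads = {k: p.grad for k, p in self.params.items() if p.grad is not None}
        if self.clip_norm is not None:
            total = math.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            p = self.params[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            p.data = p.data - self.lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps
            )

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
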