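"""Compact tape-based reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operation set the encoder needs: broadcast arithmetic,
batched matmul, embedding lookup, masked softmax, layer normalization, ReLU,
reductions, basic/boolean indexing, and a fused cross-entropy. Gradients are
accumulated on float32 arrays; correctness is checked against central finite
differences in the test suite.

Backward closures receive the upstream gradient as an argument and never
reference their own output tensor, so graphs are acyclic in the reference
graph and are freed by reference counting as soon as the outputs go out of
scope — no gc pressure during long training loops.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "embedding", "cross_entropy_with_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    n_extra = grad.ndim - len(shape)
    if n_extra > 0:
        grad = grad.sum(axis=tuple(range(n_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation tape.

    `data` is always a float32 ndarray; `grad` is allocated lazily.
    Operations record a backward closure taking the upstream gradient, plus
    their parents; `backward()` replays the tape in reverse topological order.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()
        self.name = name

    # -- graph plumbing -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def _tracked(self) -> bool:
        return self.requires_grad or bool(self._parents)

    def backward(self) -> None:
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            if t._parents:  # intermediate: its gradient is no longer needed
                t.grad = None if t is not self else t.grad

    def zero_grad(self) -> None:
        self.grad = None

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p._tracked() for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a._tracked():
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b._tracked():
                b._accumulate(_unbroadcast(g, b.data.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accumulate(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other
        a_data, b_data = a.data, b.data

        def backward(g):
            if a._tracked():
                a._accumulate(_unbroadcast(g * b_data, a_data.shape))
            if b._tracked():
                b._accumulate(_unbroadcast(g * a_data, b_data.shape))

        return self._make(a_data * b_data, (a, b), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other
        a_data, b_data = a.data, b.data

        def backward(g):
            if a._tracked():
                ga = g @ np.swapaxes(b_data, -1, -2)
                a._accumulate(_unbroadcast(ga, a_data.shape))
            if b._tracked():
                gb = np.swapaxes(a_data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b_data.shape))

        return self._make(a_data @ b_data, (a, b), backward)

    def square(self):
        return self * self

    # -- shape ops -------------------------------------------------------

    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def backward(g):
            a._accumulate(g.reshape(old))

        return self._make(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        inv = tuple(np.argsort(axes))

        def backward(g):
            a._accumulate(g.transpose(*inv))

        return self._make(a.data.transpose(*axes), (a,), backward)

    def __getitem__(self, key):
        # basic slicing / boolean masks only (no repeated fancy indices)
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            full[key] += g
            a._accumulate(full)

        return self._make(a.data[key], (a,), backward)

    # -- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities --------------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accumulate(g * mask)

        return self._make(a.data * mask, (a,), backward)

    def softmax(self, additive_mask: np.ndarray | None = None):
        """Softmax over the last axis; `additive_mask` (e.g. -1e9 on PAD keys)
        is a constant added to the logits before normalization."""
        a = self
        x = a.data
        if additive_mask is not None:
            x = x + additive_mask
        x = x - x.max(axis=-1, keepdims=True)
        e = np.exp(x)
        p = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            dot = (g * p).sum(axis=-1, keepdims=True)
            a._accumulate(p * (g - dot))

        return self._make(p, (a,), backward)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalize over the last axis, then scale/shift by gamma/beta."""
        a = self
        mu = a.data.mean(axis=-1, keepdims=True)
        xc = a.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        gamma_data = gamma.data

        def backward(g):
            if gamma._tracked():
                gamma._accumulate(_unbroadcast(g * xhat, gamma.data.shape))
            if beta._tracked():
                beta._accumulate(_unbroadcast(g, beta.data.shape))
            if a._tracked():
                gx = g * gamma_data
                term2 = gx.mean(axis=-1, keepdims=True)
                term3 = xhat * (gx * xhat).mean(axis=-1, keepdims=True)
                a._accumulate(inv * (gx - term2 - term3))

        return self._make(xhat * gamma_data + beta.data, (a, gamma, beta), backward)

    def dropout(self, rate: float, rng: np.random.Generator):
        """Inverted dropout; identity when rate == 0."""
        if rate <= 0.0:
            return self
        a = self
        keep = (rng.random(a.data.shape) >= rate).astype(np.float32) / (1.0 - rate)

        def backward(g):
            a._accumulate(g * keep)

        return self._make(a.data * keep, (a,), backward)


def embedding(table: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup `table[idx]` with scatter-add backward."""
    idx = np.asarray(idx)

    def backward(g):
        full = np.zeros_like(table.data)
        np.add.at(full, idx, g)
        table._accumulate(full)

    return table._make(table.data[idx], (table,), backward)


def cross_entropy_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-softmax probability of the true class.

    Fused op: backward is (softmax - onehot) / n, numerically stable.
    """
    labels = np.asarray(labels)
    x = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(x)
    p = e / e.sum(axis=-1, keepdims=True)
    n = labels.shape[0]
    nll = -np.log(np.maximum(p[np.arange(n), labels], 1e-30)).mean()

    def backward(g):
        gl = p.copy()
        gl[np.arange(n), labels] -= 1.0
        logits._accumulate(g * gl / n)

    return logits._make(np.float32(nll), (logits,), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
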