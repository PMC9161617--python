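"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the tensor backend for the neural event detectors.  It supports
exactly the operations the encoders and scorers need (dense affine maps,
LSTM gate arithmetic, concatenation, element-wise nonlinearities and
numerically stable classification losses) on 1-D and 2-D float64 arrays.
Gradients are accumulated by topological traversal of the recorded
operation graph.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "dot", "matvec", "row", "stack_sum", "Adam"]


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ---------------------------------------------------

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) tensor through the graph."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * Tensor(-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    # -- nonlinearities ---------------------------------------------------

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y * y))

        out._backward = bwd
        return out

    def sigmoid(self):
        y = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        out = Tensor(y, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))

        out._backward = bwd
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = bwd
        return out

    # -- reductions / reshaping ------------------------------------------

    def sum(self):
        out = Tensor(self.data.sum(), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, float(g)))

        out._backward = bwd
        return out

    def slice(self, a, b):
        out = Tensor(self.data[a:b], parents=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[a:b] = g
                self._accum(full)

        out._backward = bwd
        return out

    # -- stable losses ----------------------------------------------------

    def bce_with_logit(self, label):
        """Binary cross-entropy of sigmoid(self) against label in {0, 1}.

        Computed as softplus(x) - label * x, which is stable for large |x|.
        """
        x = float(self.data)
        loss = np.logaddexp(0.0, x) - label * x
        out = Tensor(loss, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                p = 0.5 * (1.0 + np.tanh(0.5 * x))
                self._accum(g * (p - label))

        out._backward = bwd
        return out

    def cross_entropy(self, label):
        """Softmax cross-entropy of a 1-D logit vector against class index."""
        z = self.data
        m = z.max()
        lse = m + np.log(np.exp(z - m).sum())
        out = Tensor(lse - z[label], parents=(self,))

        def bwd(g):
            if self.requires_grad:
                p = np.exp(z - lse)
                p[label] -= 1.0
                self._accum(g * p)

        out._backward = bwd
        return out

    def softmax(self):
        z = self.data
        p = np.exp(z - z.max())
        p /= p.sum()
        return p  # plain array; used at inference only

    def item(self):
        return float(self.data)


def matvec(W: Tensor, x: Tensor) -> Tensor:
    """W @ x for a 2-D weight and 1-D input."""
    out = Tensor(W.data @ x.data, parents=(W, x))

    def bwd(g):
        if W.requires_grad:
            W._accum(np.outer(g, x.data))
        if x.requires_grad:
            x._accum(W.data.T @ g)

    out._backward = bwd
    return out


def dot(w: Tensor, x: Tensor) -> Tensor:
    out = Tensor(float(w.data @ x.data), parents=(w, x))

    def bwd(g):
        if w.requires_grad:
            w._accum(g * x.data)
        if x.requires_grad:
            x._accum(g * w.data)

    out._backward = bwd
    return out


def row(W: Tensor, i: int) -> Tensor:
    """Row lookup into a 2-D parameter (embedding table)."""
    out = Tensor(W.data[i], parents=(W,))

    def bwd(g):
        if W.requires_grad:
            full = np.zeros_like(W.data)
            full[i] = g
            W._accum(full)

    out._backward = bwd
    return out


def concat(parts) -> Tensor:
    parts = list(parts)
    out = Tensor(np.concatenate([p.data for p in parts]), parents=tuple(parts))
    sizes = [p.data.shape[0] for p in parts]

    def bwd(g):
        off = 0
        for p, s in zip(parts, sizes):
            if p.requires_grad:
                p._accum(g[off : off + s])
            off += s

    out._backward = bwd
    return out


def stack_sum(parts) -> Tensor:
    """Element-wise sum of same-shaped 1-D tensors (single graph node)."""
    parts = list(parts)
    out = Tensor(np.sum([p.data for p in parts], axis=0), parents=tuple(parts))

    def bwd(g):
        for p in parts:
            if p.requires_grad:
                p._accum(g)

    out._backward = bwd
    return out


class Adam:
    """Adam optimiser over a flat list of parameter Tensors."""

    def __init__(self, params, lr=0.01, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
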