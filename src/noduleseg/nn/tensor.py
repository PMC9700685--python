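"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine purpose-built for the segmentation networks in
this package: the op set covers exactly what an encoder/decoder with
inverted-residual blocks, squeeze-excitation gates and a pyramid-attention
bridge needs (NHWC layout throughout).  Every op defines its own backward
closure; :meth:`Tensor.backward` walks the tape in reverse topological
order.  float32 is the working precision for training; the ops preserve
whatever dtype they are given, which the test-suite exploits to run
float64 finite-difference gradient checks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
            if t._parents:
                # free intermediate gradients as soon as they are consumed
                t.grad = None

    def zero_grad(self):
        self.grad = None

    # ---- elementwise -----------------------------------------------------

    def __add__(self, other):
        a, b = self, other
        out = Tensor(a.data + b.data, (a, b))

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        out._backward = bwd
        return out

    def __mul__(self, other):
        a, b = self, other
        out = Tensor(a.data * b.data, (a, b))

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        out._backward = bwd
        return out

    def relu(self):
        x = self
        out = Tensor(np.maximum(x.data, 0), (x,))

        def bwd(g):
            if x.requires_grad:
                x._accumulate(g * (x.data > 0))

        out._backward = bwd
        return out

    def sigmoid(self):
        x = self
        s = _sigmoid(x.data)
        out = Tensor(s, (x,))

        def bwd(g):
            if x.requires_grad:
                x._accumulate(g * s * (1.0 - s))

        out._backward = bwd
        return out

    def swish(self):
        """x * sigmoid(x) — smooth, non-monotone, bounded below by ~-0.2785."""
        x = self
        s = _sigmoid(x.data)
        out = Tensor(x.data * s, (x,))

        def bwd(g):
            if x.requires_grad:
                x._accumulate(g * (s + x.data * s * (1.0 - s)))

        out._backward = bwd
        return out

    # ---- dense / 1x1 conv ------------------------------------------------

    def matmul(self, w):
        """(.., Ci) @ (Ci, Co); leading axes are flattened for the GEMM."""
        x = self
        ci = x.data.shape[-1]
        x2 = x.data.reshape(-1, ci)
        out = Tensor((x2 @ w.data).reshape(x.data.shape[:-1] + (w.data.shape[1],)),
                     (x, w))

        def bwd(g):
            g2 = g.reshape(-1, w.data.shape[1])
            if x.requires_grad:
                x._accumulate((g2 @ w.data.T).reshape(x.data.shape))
            if w.requires_grad:
                w._accumulate(x2.T @ g2)

        out._backward = bwd
        return out

    # ---- reductions ------------------------------------------------------

    def mean(self):
        x = self
        out = Tensor(np.asarray(x.data.mean(), dtype=x.dtype), (x,))

        def bwd(g):
            if x.requires_grad:
                x._accumulate(np.full_like(x.data, g / x.data.size))

        out._backward = bwd
        return out

    def global_avg_pool(self):
        """(N, H, W, C) -> (N, 1, 1, C) spatial mean."""
        x = self
        n, h, w, c = x.data.shape
        out = Tensor(x.data.mean(axis=(1, 2), keepdims=True), (x,))

        def bwd(g):
            if x.requires_grad:
                x._accumulate(np.broadcast_to(g / (h * w), x.data.shape).copy())

        out._backward = bwd
        return out


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _sigmoid(x):
    # logistic via tanh: one transcendental pass, overflow-safe
    out = np.tanh(np.asarray(x) * 0.5)
    out += 1.0
    out *= 0.5
    return out


def _unbroadcast(g, shape):
    """Reduce gradient g down to `shape` by summing broadcast axes."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g
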