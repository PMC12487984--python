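"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine providing exactly the operations the trainable
potentials need: elementwise arithmetic, exp/log/cos/sqrt/softplus, matrix
products, reductions, and gather/scatter for graph aggregation.

Every backward rule is itself expressed in terms of these differentiable
operations, so gradients are `Tensor`s and can be differentiated again.
Higher-order gradients are required here: force-matching trains on forces
(-dE/dx), so the parameter gradient of the loss differentiates through a
gradient.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Tensor", "astensor", "grad"]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad=False, _parents=(), _vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents) if self.requires_grad else ()
        self._vjp = _vjp if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self):
        return Tensor(self.data)

    def item(self):
        return float(self.data)

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(other, self)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(other, self)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(other, mul(self, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(other, power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
    while g.data.ndim > len(shape):
        g = tsum(g, axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.data.shape[ax] != 1:
            g = tsum(g, axis=ax, keepdims=True)
    return g


# -- arithmetic -----------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)

    def vjp(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return Tensor(a.data + b.data, _parents=(a, b), _vjp=vjp)


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)

    def vjp(g):
        return _unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)

    return Tensor(a.data * b.data, _parents=(a, b), _vjp=vjp)


def power(a, p: float) -> Tensor:
    """Elementwise a**p for a constant exponent p."""
    a = astensor(a)
    p = float(p)

    def vjp(g):
        return (mul(g, mul(power(a, p - 1.0), p)),)

    return Tensor(a.data**p, _parents=(a,), _vjp=vjp)


def exp(a) -> Tensor:
    a = astensor(a)

    def vjp(g):
        return (mul(g, exp(a)),)

    return Tensor(np.exp(a.data), _parents=(a,), _vjp=vjp)


def log(a) -> Tensor:
    a = astensor(a)

    def vjp(g):
        return (mul(g, power(a, -1.0)),)

    return Tensor(np.log(a.data), _parents=(a,), _vjp=vjp)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def sin(a) -> Tensor:
    a = astensor(a)

    def vjp(g):
        return (mul(g, cos(a)),)

    return Tensor(np.sin(a.data), _parents=(a,), _vjp=vjp)


def cos(a) -> Tensor:
    a = astensor(a)

    def vjp(g):
        return (mul(g, mul(sin(a), -1.0)),)

    return Tensor(np.cos(a.data), _parents=(a,), _vjp=vjp)


def sigmoid(a) -> Tensor:
    a = astensor(a)

    def vjp(g):
        s = sigmoid(a)
        return (mul(g, mul(s, add(1.0, mul(s, -1.0)))),)

    # stable logistic
    out = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-a.data)),
                   np.exp(a.data) / (1.0 + np.exp(a.data)))
    return Tensor(out, _parents=(a,), _vjp=vjp)


def softplus(a) -> Tensor:
    """log(1 + e^x), computed stably; derivative is the logistic function."""
    a = astensor(a)

    def vjp(g):
        return (mul(g, sigmoid(a)),)

    return Tensor(np.logaddexp(0.0, a.data), _parents=(a,), _vjp=vjp)


def shifted_softplus(a) -> Tensor:
    """ln(0.5 e^x + 0.5): softplus shifted so f(0) = 0; smooth activation."""
    return add(softplus(a), -math.log(2.0))


# -- shape ops ------------------------------------------------------------


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    old = a.shape

    def vjp(g):
        return (reshape(g, old),)

    return Tensor(a.data.reshape(shape), _parents=(a,), _vjp=vjp)


def transpose(a) -> Tensor:
    a = astensor(a)

    def vjp(g):
        return (transpose(g),)

    return Tensor(a.data.T, _parents=(a,), _vjp=vjp)


def broadcast_to(a, shape) -> Tensor:
    a = astensor(a)
    old = a.shape

    def vjp(g):
        return (_unbroadcast(g, old),)

    return Tensor(np.broadcast_to(a.data, shape), _parents=(a,), _vjp=vjp)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    shape = a.shape

    def vjp(g):
        if axis is None:
            return (broadcast_to(reshape(g, (1,) * len(shape)), shape),)
        if not keepdims:
            kshape = list(g.data.shape)
            kshape.insert(axis if axis >= 0 else len(shape) + axis, 1)
            g = reshape(g, tuple(kshape))
        return (broadcast_to(g, shape),)

    return Tensor(np.sum(a.data, axis=axis, keepdims=keepdims), _parents=(a,), _vjp=vjp)


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)

    def vjp(g):
        return matmul(g, transpose(b)), matmul(transpose(a), g)

    return Tensor(a.data @ b.data, _parents=(a, b), _vjp=vjp)


# -- graph gather / scatter ------------------------------------------------


def gather(a, idx) -> Tensor:
    """Row selection a[idx] along axis 0; adjoint is scatter_add."""
    a = astensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    n = a.shape[0]

    def vjp(g):
        return (scatter_add(g, idx, n),)

    return Tensor(a.data[idx], _parents=(a,), _vjp=vjp)


def scatter_add(a, idx, n: int) -> Tensor:
    """Sum rows of ``a`` into ``n`` bins given by ``idx``; adjoint is gather."""
    a = astensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    out = np.zeros((n,) + a.shape[1:], dtype=np.float64)
    np.add.at(out, idx, a.data)

    def vjp(g):
        return (gather(g, idx),)

    return Tensor(out, _parents=(a,), _vjp=vjp)


# -- reverse pass ----------------------------------------------------------


def _topo_order(root: Tensor):
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    return order


def grad(output: Tensor, inputs, grad_output=None):
    """Gradients of ``output`` w.r.t. each tensor in ``inputs``.

    The returned gradients are themselves graph nodes, so they can be fed
    back into :func:`grad` for higher-order derivatives.
    """
    single = isinstance(inputs, Tensor)
    inputs = [inputs] if single else list(inputs)
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    grads: dict[int, Tensor] = {id(output): astensor(grad_output)}
    for node in reversed(_topo_order(output)):
        g = grads.get(id(node))
        if g is None or node._vjp is None:
            continue
        parent_grads = node._vjp(g)
        for p, pg in zip(node._parents, parent_grads):
            if pg is None or not p.requires_grad:
                continue
            if id(p) in grads:
                grads[id(p)] = add(grads[id(p)], pg)
            else:
                grads[id(p)] = pg
    out = [grads.get(id(x), Tensor(np.zeros_like(x.data))) for x in inputs]
    return out[0] if single else out
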