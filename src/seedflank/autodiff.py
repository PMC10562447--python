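"""Minimal reverse-mode automatic differentiation on numpy arrays.

Every vector-Jacobian product is itself expressed in terms of traced tensor
operations, so gradients of gradients are exact: this is what lets the
Wasserstein critic train against a gradient-norm penalty without resorting to
finite-difference surrogates.  The engine is deliberately small — only the
operations the sequence models need — and works in float64 throughout.
"""

from __future__ import annotations

import contextlib

import numpy as np

_TRACE = True  # module-level switch: when False, new ops record no parents


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference fast path)."""
    global _TRACE
    old, _TRACE = _TRACE, False
    try:
        yield
    finally:
        _TRACE = old


class Tensor:
    """A numpy array plus the tape entry that produced it."""

    __slots__ = ("data", "parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = parents  # tuple of (parent Tensor, vjp callable)
        self.requires_grad = requires_grad

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

    # operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __getitem__(self, key):
        return getitem(self, key)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def _make(data, parents) -> Tensor:
    if _TRACE and any(p.requires_grad for p, _ in parents):
        return Tensor(data, tuple(parents), requires_grad=True)
    return Tensor(data)


# ---------------------------------------------------------------------------
# broadcasting helpers

def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Sum-reduce gradient ``g`` back to ``shape`` (inverse of broadcasting)."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = reshape(g, shape)
    return g


def broadcast_to(x: Tensor, shape) -> Tensor:
    x = _as_tensor(x)
    shape = tuple(shape)
    out = np.broadcast_to(x.data, shape)
    return _make(np.ascontiguousarray(out), [(x, lambda g: _unbroadcast(g, x.shape))])


# ---------------------------------------------------------------------------
# elementwise ops

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(a.data + b.data, [(a, lambda g: _unbroadcast(g, a.shape)),
                                   (b, lambda g: _unbroadcast(g, b.shape))])


def sub(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(a.data - b.data, [(a, lambda g: _unbroadcast(g, a.shape)),
                                   (b, lambda g: _unbroadcast(neg(g), b.shape))])


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(a.data * b.data, [(a, lambda g: _unbroadcast(mul(g, b), a.shape)),
                                   (b, lambda g: _unbroadcast(mul(g, a), b.shape))])


def div(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(a.data / b.data,
                 [(a, lambda g: _unbroadcast(div(g, b), a.shape)),
                  (b, lambda g: _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape))])


def neg(a):
    a = _as_tensor(a)
    return _make(-a.data, [(a, lambda g: neg(g))])


# VJPs below are traced expressions of the inputs (not cached values) so that
# differentiating a gradient graph a second time remains exact.

def exp(a):
    a = _as_tensor(a)
    return _make(np.exp(a.data), [(a, lambda g: mul(g, exp(a)))])


def log(a):
    a = _as_tensor(a)
    return _make(np.log(a.data), [(a, lambda g: div(g, a))])


def tanh(a):
    a = _as_tensor(a)
    return _make(np.tanh(a.data),
                 [(a, lambda g: mul(g, sub(1.0, mul(tanh(a), tanh(a)))))])


def sigmoid(a):
    a = _as_tensor(a)
    return _make(1.0 / (1.0 + np.exp(-a.data)),
                 [(a, lambda g: mul(g, mul(sigmoid(a), sub(1.0, sigmoid(a)))))])


def relu(a):
    a = _as_tensor(a)
    mask = (a.data > 0).astype(np.float64)
    return _make(a.data * mask, [(a, lambda g, m=mask: mul(g, Tensor(m)))])


def power(a, p: float):
    a = _as_tensor(a)
    return _make(a.data ** p,
                 [(a, lambda g: mul(g, mul(p, power(a, p - 1.0))))])


def sqrt(a):
    return power(a, 0.5)


def absolute(a):
    a = _as_tensor(a)
    sign = np.sign(a.data)
    return _make(np.abs(a.data), [(a, lambda g, s=sign: mul(g, Tensor(s)))])


# ---------------------------------------------------------------------------
# shape ops

def reshape(a, shape):
    a = _as_tensor(a)
    shape = tuple(shape)
    return _make(a.data.reshape(shape), [(a, lambda g: reshape(g, a.shape))])


def transpose(a, axes):
    a = _as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _make(np.ascontiguousarray(a.data.transpose(axes)),
                 [(a, lambda g: transpose(g, inv))])


def swap_last(a):
    """Swap the last two axes (used by matmul VJPs)."""
    a = _as_tensor(a)
    axes = tuple(range(a.ndim - 2)) + (a.ndim - 1, a.ndim - 2)
    return transpose(a, axes)


def concat(tensors, axis=0):
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    parents = []
    start = 0
    for t in tensors:
        n = t.data.shape[axis]
        key = [slice(None)] * data.ndim
        key[axis] = slice(start, start + n)
        parents.append((t, lambda g, k=tuple(key): getitem(g, k)))
        start += n
    return _make(data, parents)


def getitem(a, key):
    a = _as_tensor(a)
    return _make(a.data[key], [(a, lambda g: scatter(g, key, a.shape))])


def scatter(g, key, shape):
    """Place ``g`` into zeros of ``shape`` at ``key`` (adjoint of getitem)."""
    g = _as_tensor(g)
    out = np.zeros(shape, dtype=np.float64)
    np.add.at(out, key, g.data)
    return _make(out, [(g, lambda gg: getitem(gg, key))])


# ---------------------------------------------------------------------------
# reductions and matmul

def tsum(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return broadcast_to(reshape(g, (1,) * a.ndim), a.shape)
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(ax % a.ndim for ax in axes)
        if not keepdims:
            kshape = tuple(1 if i in axes else s for i, s in enumerate(a.shape))
            g = reshape(g, kshape)
        return broadcast_to(g, a.shape)

    return _make(out, [(a, vjp)])


def tmean(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return div(tsum(a, axis=axis, keepdims=keepdims), float(n))


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data @ b.data

    def vjp_a(g):
        ga = matmul(g, swap_last(b))
        return _unbroadcast(ga, a.shape) if ga.shape != a.shape else ga

    def vjp_b(g):
        gb = matmul(swap_last(a), g)
        return _unbroadcast(gb, b.shape) if gb.shape != b.shape else gb

    return _make(out, [(a, vjp_a), (b, vjp_b)])


def softmax(a, axis=-1):
    a = _as_tensor(a)
    shift = Tensor(a.data.max(axis=axis, keepdims=True))  # constant: softmax invariant
    e = exp(sub(a, shift))
    return div(e, tsum(e, axis=axis, keepdims=True))


def logsumexp(a, axis=-1):
    a = _as_tensor(a)
    shift = Tensor(a.data.max(axis=axis, keepdims=True))
    return add(log(tsum(exp(sub(a, shift)), axis=axis, keepdims=True)), shift)


# ---------------------------------------------------------------------------
# backward

def grad(output: Tensor, inputs, create_graph: bool = False):
    """Gradients of a scalar ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned gradients are themselves nodes of a
    traced graph and can be differentiated again (double backprop).
    """
    global _TRACE
    if output.data.size != 1:
        raise ValueError("grad expects a scalar output")
    topo, seen = [], set()
    stack = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p, _ in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    grads = {id(output): Tensor(np.ones_like(output.data))}
    keep = {id(t) for t in inputs}
    old, _TRACE = _TRACE, create_graph
    try:
        for node in reversed(topo):
            g = grads.get(id(node))
            if g is None:
                continue
            if id(node) not in keep:
                del grads[id(node)]
            for p, vjp in node.parents:
                if not p.requires_grad:
                    continue
                pg = vjp(g)
                if id(p) in grads:
                    grads[id(p)] = add(grads[id(p)], pg)
                else:
                    grads[id(p)] = pg
    finally:
        _TRACE = old
    out = []
    for t in inputs:
        gt = grads.get(id(t))
        if gt is None:
            gt = Tensor(np.zeros_like(t.data))
        out.append(gt)
    return out
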