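"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports higher-order gradients: every backward rule is itself expressed
in terms of :class:`Tensor` operations, so the gradient of a gradient can
be taken — which the Wasserstein gradient-penalty objective requires
(differentiating the critic's input-gradient norm with respect to the
critic's parameters).

Only the operations the adaptor/critic networks need are implemented:
elementwise arithmetic, matmul, reductions, reshape/swap/slice/pad/concat,
tanh, leaky-ReLU and sigmoid.  :func:`grad` prunes the backward sweep to
the subgraph that actually reaches the requested inputs, so e.g. the
input-gradient inside the penalty term skips all parameter paths.

Float32 data is kept in float32 (the networks train in single precision);
everything else is promoted to float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "grad", "concat", "narrow", "pad_axis", "broadcast_to"]

_FLOAT_TYPES = (np.float32, np.float64)


def _as_array(data):
    a = np.asarray(data)
    if a.dtype.type in _FLOAT_TYPES:
        return a
    return a.astype(np.float64)


class Tensor:
    """A NumPy array plus the graph edges needed for backpropagation."""

    __slots__ = ("data", "parents", "vjps", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), vjps=()):
        self.data = _as_array(data)
        if not requires_grad:
            for p in parents:
                if p.requires_grad:
                    requires_grad = True
                    break
        self.requires_grad = requires_grad
        if requires_grad:
            self.parents = parents
            self.vjps = vjps
        else:  # drop graph edges for constants
            self.parents = ()
            self.vjps = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------
    # python scalars stay raw so NumPy's weak promotion keeps float32
    def __add__(self, other):
        a = self
        if isinstance(other, (int, float)):
            return Tensor(a.data + other, parents=(a,), vjps=(lambda g: g,))
        b = _wrap(other)
        return Tensor(
            a.data + b.data,
            parents=(a, b),
            vjps=(
                lambda g: _unbroadcast(g, a.shape),
                lambda g: _unbroadcast(g, b.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), vjps=(lambda g: -g,))

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-_wrap(other))

    def __rsub__(self, other):
        a = self
        if isinstance(other, (int, float)):
            return Tensor(other - a.data, parents=(a,), vjps=(lambda g: -g,))
        return _wrap(other) + (-self)

    def __mul__(self, other):
        a = self
        if isinstance(other, (int, float)):
            return Tensor(a.data * other, parents=(a,), vjps=(lambda g: g * other,))
        b = _wrap(other)
        return Tensor(
            a.data * b.data,
            parents=(a, b),
            vjps=(
                lambda g: _unbroadcast(g * b, a.shape),
                lambda g: _unbroadcast(g * a, b.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        a = self
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        b = _wrap(other)
        return Tensor(
            a.data / b.data,
            parents=(a, b),
            vjps=(
                lambda g: _unbroadcast(g / b, a.shape),
                lambda g: _unbroadcast(-g * a / (b * b), b.shape),
            ),
        )

    def __rtruediv__(self, other):
        a = self
        if isinstance(other, (int, float)):
            return Tensor(
                other / a.data,
                parents=(a,),
                vjps=(lambda g: -g * other / (a * a),),
            )
        return _wrap(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        a = self
        return Tensor(
            a.data**p,
            parents=(a,),
            vjps=(lambda g: g * (p * a ** (p - 1)),),
        )

    def __matmul__(self, other):
        a, b = self, _wrap(other)
        if a.ndim < 2 or b.ndim < 2:
            raise ValueError("matmul operands must be at least 2-D")
        if a.ndim == 2 and b.ndim == 2:
            vjps = (
                lambda g: g @ b.swapaxes(-1, -2),
                lambda g: a.swapaxes(-1, -2) @ g,
            )
        else:
            vjps = (
                lambda g: _unbroadcast(g @ b.swapaxes(-1, -2), a.shape),
                lambda g: _unbroadcast(a.swapaxes(-1, -2) @ g, b.shape),
            )
        return Tensor(a.data @ b.data, parents=(a, b), vjps=vjps)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if axis is None:
                return broadcast_to(g.reshape((1,) * a.ndim), a.shape)
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            axes = tuple(ax % a.ndim for ax in axes)
            if not keepdims:
                kd_shape = tuple(
                    1 if i in axes else s for i, s in enumerate(a.shape)
                )
                g = g.reshape(kd_shape)
            return broadcast_to(g, a.shape)

        return Tensor(out_data, parents=(a,), vjps=(vjp,))

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.shape[ax % self.ndim] for ax in ((axis,) if np.isscalar(axis) else axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    # -- shape ops -----------------------------------------------------
    def reshape(self, shape):
        a = self
        return Tensor(
            a.data.reshape(shape),
            parents=(a,),
            vjps=(lambda g: g.reshape(a.shape),),
        )

    def swapaxes(self, a1: int, a2: int):
        a = self
        return Tensor(
            a.data.swapaxes(a1, a2),
            parents=(a,),
            vjps=(lambda g: g.swapaxes(a1, a2),),
        )

    # -- nonlinearities ------------------------------------------------
    def tanh(self):
        a = self
        out = Tensor(np.tanh(a.data), parents=(a,))
        if out.requires_grad:
            out.vjps = (lambda g: g * (1.0 - out * out),)
        return out

    def leaky_relu(self, slope: float = 0.2):
        a = self
        mask = np.where(a.data > 0, a.data.dtype.type(1.0), a.data.dtype.type(slope))
        return Tensor(
            a.data * mask,
            parents=(a,),
            vjps=(lambda g: g * Tensor(mask),),
        )

    def sigmoid(self):
        a = self
        out = Tensor(1.0 / (1.0 + np.exp(-a.data)), parents=(a,))
        if out.requires_grad:
            out.vjps = (lambda g: g * out * (1.0 - out),)
        return out


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def broadcast_to(x: Tensor, shape) -> Tensor:
    x = _wrap(x)
    if x.shape == tuple(shape):
        return x
    return Tensor(
        np.broadcast_to(x.data, shape),
        parents=(x,),
        vjps=(lambda g: _unbroadcast(g, x.shape),),
    )


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce a gradient back to the shape of a broadcast operand."""
    if g.shape == shape:
        return g
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice along one axis; adjoint of zero padding."""
    x = _wrap(x)
    idx = [slice(None)] * x.ndim
    idx[axis] = slice(start, start + length)
    after = x.shape[axis] - start - length
    return Tensor(
        x.data[tuple(idx)],
        parents=(x,),
        vjps=(lambda g: pad_axis(g, axis, start, after),),
    )


def pad_axis(x: Tensor, axis: int, before: int, after: int) -> Tensor:
    """Zero-pad along one axis; adjoint of :func:`narrow`."""
    x = _wrap(x)
    if before == 0 and after == 0:
        return x
    pads = [(0, 0)] * x.ndim
    pads[axis] = (before, after)
    length = x.shape[axis]
    return Tensor(
        np.pad(x.data, pads),
        parents=(x,),
        vjps=(lambda g: narrow(g, axis, before, length),),
    )


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    axis = axis % tensors[0].ndim
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def make_vjp(i):
        return lambda g: narrow(g, axis, int(offsets[i]), sizes[i])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        vjps=tuple(make_vjp(i) for i in range(len(tensors))),
    )


def grad(output: Tensor, inputs, grad_output: Tensor | None = None) -> list[Tensor]:
    """Gradients of ``output`` w.r.t. ``inputs``.

    The returned tensors are themselves graph nodes, so they can be
    differentiated again (double backward).  ``output`` must be scalar
    unless ``grad_output`` is given.  The sweep only visits graph nodes
    on a path from ``inputs`` to ``output``.
    """
    inputs = list(inputs)
    if grad_output is None:
        if output.data.size != 1:
            raise ValueError("grad of a non-scalar needs an explicit grad_output")
        grad_output = Tensor(np.ones_like(output.data))

    # iterative topological sort (post-order: parents before consumers)
    topo: list[Tensor] = []
    state: dict[int, int] = {}
    stack = [output]
    while stack:
        node = stack.pop()
        nid = id(node)
        if state.get(nid) == 2:
            continue
        if state.get(nid) == 1:
            state[nid] = 2
            topo.append(node)
            continue
        state[nid] = 1
        stack.append(node)
        for p in node.parents:
            if p.requires_grad and state.get(id(p)) != 2:
                stack.append(p)

    # prune: only nodes that can reach a requested input matter
    input_ids = {id(i) for i in inputs}
    reaches: dict[int, bool] = {}
    for node in topo:
        nid = id(node)
        r = nid in input_ids
        if not r:
            for p in node.parents:
                if reaches.get(id(p)):
                    r = True
                    break
        reaches[nid] = r

    grads: dict[int, Tensor] = {id(output): grad_output}
    for node in reversed(topo):
        nid = id(node)
        if not reaches.get(nid):
            continue
        g = grads.get(nid)
        if g is None:
            continue
        for parent, vjp in zip(node.parents, node.vjps):
            if not parent.requires_grad or not reaches.get(id(parent)):
                continue
            contrib = vjp(g)
            pid = id(parent)
            grads[pid] = contrib if pid not in grads else grads[pid] + contrib

    return [
        grads.get(id(i)) if grads.get(id(i)) is not None else Tensor(np.zeros_like(i.data))
        for i in inputs
    ]
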