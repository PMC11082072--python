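"""Minimal reverse-mode automatic differentiation over numpy arrays.

The classifier towers, losses, optimizer steps, and integrated-gradients
attribution all run on this engine. It is a vectorized tape: each
:class:`Tensor` wraps an ndarray, records its parents and a closure that
accumulates gradients into them, and ``backward()`` walks the tape in
reverse topological order. Broadcasting is supported on elementwise ops
and matmul batch dimensions; gradients are summed back to parent shapes.

Only the operations the package needs are implemented. Gradients are
accumulated in float64 throughout — at the problem sizes this package
targets (peptides up to ~100 tokens, batches of tens), clarity and
reproducibility beat throughput.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple["Tensor", ...] = (),
                 _backward: Optional[Callable[[Array], None]] = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[Array] = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd driver -----------------------------------------------------
    def backward(self, grad: Optional[Array] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, Array] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if parent.requires_grad or parent._backward is not None:
                        key = id(parent)
                        if key in grads:
                            grads[key] = grads[key] + pg
                        else:
                            grads[key] = pg

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = ensure_tensor(other)
        out_data = self.data + other.data

        def back(g):
            return ((self, _unbroadcast(g, self.shape)),
                    (other, _unbroadcast(g, other.shape)))

        return Tensor(out_data, _parents=(self, other), _backward=back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            return ((self, -g),)
        return Tensor(-self.data, _parents=(self,), _backward=back)

    def __sub__(self, other):
        return self + (-ensure_tensor(other))

    def __rsub__(self, other):
        return ensure_tensor(other) + (-self)

    def __mul__(self, other):
        other = ensure_tensor(other)
        out_data = self.data * other.data

        def back(g):
            return ((self, _unbroadcast(g * other.data, self.shape)),
                    (other, _unbroadcast(g * self.data, other.shape)))

        return Tensor(out_data, _parents=(self, other), _backward=back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = ensure_tensor(other)
        out_data = self.data / other.data

        def back(g):
            return ((self, _unbroadcast(g / other.data, self.shape)),
                    (other, _unbroadcast(-g * self.data / other.data ** 2,
                                         other.shape)))

        return Tensor(out_data, _parents=(self, other), _backward=back)

    def __rtruediv__(self, other):
        return ensure_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def back(g):
            return ((self, g * exponent * self.data ** (exponent - 1)),)

        return Tensor(out_data, _parents=(self,), _backward=back)

    def __matmul__(self, other):
        other = ensure_tensor(other)
        out_data = self.data @ other.data

        def back(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return ((self, _unbroadcast(ga, self.shape)),
                    (other, _unbroadcast(gb, other.shape)))

        return Tensor(out_data, _parents=(self, other), _backward=back)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def back(g):
            return ((self, g * out_data),)

        return Tensor(out_data, _parents=(self,), _backward=back)

    def log(self):
        def back(g):
            return ((self, g / self.data),)

        return Tensor(np.log(self.data), _parents=(self,), _backward=back)

    def tanh(self):
        out_data = np.tanh(self.data)

        def back(g):
            return ((self, g * (1.0 - out_data ** 2)),)

        return Tensor(out_data, _parents=(self,), _backward=back)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def back(g):
            return ((self, g * out_data * (1.0 - out_data)),)

        return Tensor(out_data, _parents=(self,), _backward=back)

    def relu(self):
        keep = self.data > 0

        def back(g):
            return ((self, g * keep),)

        return Tensor(self.data * keep, _parents=(self,), _backward=back)

    def sqrt(self):
        return self ** 0.5

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through strictly inside (lo, hi)."""
        inside = (self.data > lo) & (self.data < hi)

        def back(g):
            return ((self, g * inside),)

        return Tensor(np.clip(self.data, lo, hi), _parents=(self,), _backward=back)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.shape).copy()),)

        return Tensor(out_data, _parents=(self,), _backward=back)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; ties route the gradient to the first argmax."""
        arg = np.argmax(self.data, axis=axis)
        out_data = np.max(self.data, axis=axis, keepdims=keepdims)

        def back(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(arg, axis), g, axis=axis)
            return ((self, full),)

        return Tensor(out_data, _parents=(self,), _backward=back)

    # -- shape manipulation ----------------------------------------------------
    def reshape(self, *shape):
        old_shape = self.shape

        def back(g):
            return ((self, g.reshape(old_shape)),)

        return Tensor(self.data.reshape(*shape), _parents=(self,), _backward=back)

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)

        def back(g):
            return ((self, g.transpose(inv)),)

        return Tensor(self.data.transpose(axes), _parents=(self,), _backward=back)

    def swapaxes(self, a: int, b: int):
        def back(g):
            return ((self, np.swapaxes(g, a, b)),)

        return Tensor(np.swapaxes(self.data, a, b), _parents=(self,), _backward=back)

    def __getitem__(self, key):
        advanced = _is_advanced(key)

        def back(g):
            full = np.zeros_like(self.data)
            if advanced:
                np.add.at(full, key, g)
            else:
                full[key] += g
            return ((self, full),)

        return Tensor(self.data[key], _parents=(self,), _backward=back)


def _is_advanced(key) -> bool:
    items = key if isinstance(key, tuple) else (key,)
    return any(isinstance(k, (np.ndarray, list)) for k in items)


def ensure_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [ensure_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)

    def back(g):
        parts = np.split(g, splits, axis=axis)
        return tuple((t, p) for t, p in zip(tensors, parts))

    return Tensor(out_data, _parents=tuple(tensors), _backward=back)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        shape = list(t.shape)
        shape.insert(axis if axis >= 0 else len(shape) + axis + 1, 1)
        expanded.append(t.reshape(*shape))
    return concatenate(expanded, axis=axis)


def embedding_lookup(weight: Tensor, indices: Array) -> Tensor:
    """Gather rows of an embedding table; backward scatter-adds."""
    indices = np.asarray(indices, dtype=np.int64)

    def back(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, indices.reshape(-1), g.reshape(-1, weight.data.shape[1]))
        return ((weight, full),)

    return Tensor(weight.data[indices], _parents=(weight,), _backward=back)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stabilized softmax (constant max-shift, exact gradient)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def numerical_gradient(f: Callable[[Array], float], x: Array,
                       eps: float = 1e-6) -> Array:
    """Central-difference gradient of a scalar function; test oracle only."""
    x = np.asarray(x, dtype=np.float64)
    grad = np.zeros_like(x)
    flat = x.reshape(-1)
    gflat = grad.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f(x)
        flat[i] = orig - eps
        lo = f(x)
        flat[i] = orig
        gflat[i] = (hi - lo) / (2 * eps)
    return grad
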