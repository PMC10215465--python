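"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The trainable models in this package (transformer encoder, graph-attention
sublayer, slim decoder) are small enough that a tape-based scalar-of-arrays
engine is entirely adequate: every operation records its parents and a
closure that accumulates gradients, and :meth:`Tensor.backward` walks the
tape in reverse topological order.

Only the operations the models need are implemented.  Broadcasting follows
NumPy semantics; gradients of broadcast operands are summed back to the
operand's shape.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


def _as_array(x) -> Array:
    return x if isinstance(x, np.ndarray) else np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # Sum over leading axes added by broadcasting.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # Sum over axes that were size 1 in the original.
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[Array], None] | None = None,
    ):
        self.data = _as_array(data).astype(np.float64, copy=False)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- bookkeeping ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: Array) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad: Array | None = None) -> None:
        """Backpropagate from this node; `grad` defaults to 1 for scalars."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other) -> "Tensor":
        return Tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return Tensor(self.data / other.data, parents=(self, other), backward=bwd)

    def __matmul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g: Array) -> None:
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor(self.data @ other.data, parents=(self, other), backward=bwd)

    def pow(self, exponent: float) -> "Tensor":
        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(self.data**exponent, parents=(self,), backward=bwd)

    # -- reductions / shaping --------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bwd(g: Array) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bwd
        )

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        old = self.shape

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    def transpose(self, *axes) -> "Tensor":
        axes_ = axes or None

        def bwd(g: Array) -> None:
            if self.requires_grad:
                if axes_ is None:
                    self._accumulate(g.transpose())
                else:
                    inv = np.argsort(axes_)
                    self._accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(*axes), parents=(self,), backward=bwd)

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def __getitem__(self, idx) -> "Tensor":
        def bwd(g: Array) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor(self.data[idx], parents=(self,), backward=bwd)

    # -- nonlinearities ---------------------------------------------------

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self) -> "Tensor":
        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bwd)

    def leaky_relu(self, negative_slope: float = 0.2) -> "Tensor":
        slope = np.where(self.data > 0, 1.0, negative_slope)

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * slope)

        return Tensor(self.data * slope, parents=(self,), backward=bwd)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)


# -- free functions -------------------------------------------------------


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g: Array) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=bwd,
    )


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)

    def bwd(g: Array) -> None:
        parts = np.moveaxis(g, axis, 0)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(part)

    return Tensor(
        np.stack([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=bwd,
    )


def embedding(table: Tensor, ids: Iterable[int]) -> Tensor:
    """Row lookup into `table`; gradient scatter-adds into the table."""
    idx = np.asarray(list(ids), dtype=np.int64)

    def bwd(g: Array) -> None:
        if table.requires_grad:
            full = np.zeros_like(table.data)
            np.add.at(full, idx, g)
            table._accumulate(full)

    return Tensor(table.data[idx], parents=(table,), backward=bwd)


def softmax(x: Tensor, axis: int = -1, bias: Array | None = None) -> Tensor:
    """Numerically stable softmax; `bias` (e.g. -inf-like mask) is added
    to the logits without entering the gradient path."""
    shift = x
    if bias is not None:
        shift = x + Tensor(bias)
    # Subtracting a detached max is gradient-neutral.
    m = np.max(shift.data, axis=axis, keepdims=True)
    e = (shift - Tensor(m)).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = np.max(x.data, axis=axis, keepdims=True)
    shifted = x - Tensor(m)
    lse = shifted.exp().sum(axis=axis, keepdims=True).log()
    return shifted - lse


def cross_entropy_logits(logits: Tensor, target_index: int) -> Tensor:
    """Negative log-likelihood of `target_index` under softmax(logits)."""
    logp = log_softmax(logits, axis=-1)
    flat = logp.reshape(-1)
    return -flat[np.array([target_index])].sum()


def parameter(rng: np.random.Generator, *shape: int, scale: float = 0.02) -> Tensor:
    """A trainable tensor initialized from N(0, scale^2)."""
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


def zeros(*shape: int, requires_grad: bool = True) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=requires_grad)


def ones(*shape: int, requires_grad: bool = True) -> Tensor:
    return Tensor(np.ones(shape), requires_grad=requires_grad)
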