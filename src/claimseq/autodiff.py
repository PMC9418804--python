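"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine providing exactly the operations the sequence
models need: broadcast arithmetic, matmul, pointwise nonlinearities,
reductions with max/cumulative-max (gradients routed to the first argmax),
gather (embedding lookup) with scatter-add backward, concatenation and
reshaping.  Gradients are accumulated into ``.grad`` by calling
``backward()`` on a scalar.  An Adam optimizer with per-step parameter
freezing supports the two-stage fine-tuning schedule.
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "where", "softmax", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over broadcast dimensions so it matches ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / other.data)
            if other.requires_grad:
                other._accumulate(-g * self.data / other.data**2)

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return self._make(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    # -- pointwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g / (2.0 * out_data))

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accumulate(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def softplus(self):
        """log(1 + e^x), computed stably as logaddexp(0, x)."""
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            self._accumulate(g * sig)

        return self._make(out_data, (self,), backward)

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                gk = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gk, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Maximum along ``axis``; gradient flows to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(
            self.data, np.expand_dims(idx, axis), axis=axis
        )

        def backward(g):
            gk = g if keepdims else np.expand_dims(g, axis)
            grad = np.zeros_like(self.data)
            np.put_along_axis(grad, np.expand_dims(idx, axis), gk, axis=axis)
            self._accumulate(grad)

        data = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return self._make(data, (self,), backward)

    def cummax(self, axis: int):
        """Running maximum along ``axis``.

        Backward scatters each output position's gradient to the earliest
        input position achieving the running maximum — the same first-argmax
        convention as :meth:`max`.
        """
        out_data = np.maximum.accumulate(self.data, axis=axis)
        # source[j] = earliest index i <= j with data[i] == cummax[j]
        ar = np.arange(self.data.shape[axis])
        shape = [1] * self.data.ndim
        shape[axis] = -1
        ar = ar.reshape(shape)
        prev = np.roll(out_data, 1, axis=axis)
        first = [slice(None)] * self.data.ndim
        first[axis] = slice(0, 1)
        prev[tuple(first)] = -np.inf
        is_new_max = self.data > prev  # strictly improves the running max
        src = np.where(is_new_max, ar, 0)
        src = np.maximum.accumulate(src, axis=axis)

        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(
                grad,
                tuple(
                    src if d == axis else np.indices(g.shape)[d]
                    for d in range(g.ndim)
                ),
                g,
            )
            self._accumulate(grad)

        return self._make(out_data, (self,), backward)

    # -- shape & indexing ---------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, key, g)
            self._accumulate(grad)

        return self._make(self.data[key], (self,), backward)

    def take_rows(self, indices: np.ndarray):
        """Embedding gather: rows of a 2-D table by an integer index array."""
        indices = np.asarray(indices)

        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, indices.reshape(-1), g.reshape(-1, self.data.shape[1]))
            self._accumulate(grad)

        return self._make(self.data[indices], (self,), backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            pieces = np.split(g, offsets[1:-1], axis=axis)
            for t, piece in zip(tensors, pieces):
                if t.requires_grad:
                    t._accumulate(piece)

        out._backward = backward
    return out


def where(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Elementwise select with a constant boolean mask."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    out = Tensor(np.where(mask, a.data, b.data))
    if a.requires_grad or b.requires_grad:
        out.requires_grad = True
        out._parents = (a, b)

        def backward(g):
            if a.requires_grad:
                a._accumulate(np.where(mask, g, 0.0))
            if b.requires_grad:
                b._accumulate(np.where(mask, 0.0, g))

        out._backward = backward
    return out


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max-shift treated as a constant)."""
    shift = Tensor(t.data.max(axis=axis, keepdims=True))
    e = (t - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adaptive-moment optimizer over a named parameter dict.

    ``step(freeze=...)`` skips both the update *and* the moment bookkeeping
    for frozen parameters, so a frozen tensor is bit-identical afterwards.
    """

    def __init__(
        self,
        params: Mapping[str, Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self._m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self._t = {k: 0 for k in self.params}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self, freeze: Iterable[str] = ()) -> None:
        frozen = set(freeze)
        for name, p in self.params.items():
            if name in frozen or p.grad is None:
                continue
            self._t[name] += 1
            t = self._t[name]
            m = self._m[name] = self.b1 * self._m[name] + (1 - self.b1) * p.grad
            v = self._v[name] = self.b2 * self._v[name] + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**t)
            vhat = v / (1 - self.b2**t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
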