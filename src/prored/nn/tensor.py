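"""A small reverse-mode autodiff engine on NumPy arrays.

Only what the segmentation model needs: broadcasting elementwise arithmetic,
(batched) matmul, reductions, reshape/transpose, ReLU, softmax and
concatenation.  Convolution, pooling, resizing and the directional-field warp
live in :mod:`prored.nn.functional` and register themselves through the same
``Tensor`` node mechanism.

Everything is float32.  Gradients accumulate into ``Tensor.grad`` (a NumPy
array) during :meth:`Tensor.backward`, which walks the tape in reverse
topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the adjoint of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _binary(a: "Tensor", b: "Tensor", out_data, da, db) -> "Tensor":
        req = a.requires_grad or b.requires_grad

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(da(g), a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(db(g), b.data.shape))

        return Tensor(out_data, req, (a, b), bwd if req else None)

    def __add__(self, other):
        other = as_tensor(other)
        return self._binary(self, other, self.data + other.data, lambda g: g, lambda g: g)

    __radd__ = __add__

    def __sub__(self, other):
        other = as_tensor(other)
        return self._binary(self, other, self.data - other.data, lambda g: g, lambda g: -g)

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __neg__(self):
        return self * -1.0

    def __mul__(self, other):
        other = as_tensor(other)
        return self._binary(
            self, other, self.data * other.data,
            lambda g: g * other.data, lambda g: g * self.data,
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return self._binary(
            self, other, self.data / other.data,
            lambda g: g / other.data,
            lambda g: -g * self.data / (other.data * other.data),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = self.data ** exponent
        req = self.requires_grad

        def bwd(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(out, req, (self,), bwd if req else None)

    def sqrt(self):
        return self ** 0.5

    def exp(self):
        out = np.exp(self.data)
        req = self.requires_grad

        def bwd(g):
            self._accumulate(g * out)

        return Tensor(out, req, (self,), bwd if req else None)

    def log(self):
        req = self.requires_grad

        def bwd(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), req, (self,), bwd if req else None)

    # --------------------------------------------------------------- matmul
    def __matmul__(self, other):
        other = as_tensor(other)
        out = np.matmul(self.data, other.data)
        req = self.requires_grad or other.requires_grad

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor(out, req, (self, other), bwd if req else None)

    # ----------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)
        req = self.requires_grad
        shape = self.data.shape

        def bwd(g):
            if axis is not None and not keepdims:
                ax = (axis,) if isinstance(axis, int) else tuple(axis)
                ax = tuple(a % len(shape) for a in ax)
                g = np.expand_dims(g, tuple(sorted(ax)))
            self._accumulate(np.broadcast_to(g, shape).astype(np.float32))

        return Tensor(out, req, (self,), bwd if req else None)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self.data.reshape(shape)
        req = self.requires_grad
        orig = self.data.shape

        def bwd(g):
            self._accumulate(g.reshape(orig))

        return Tensor(out, req, (self,), bwd if req else None)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = self.data.transpose(axes)
        req = self.requires_grad
        inv = np.argsort(axes)

        def bwd(g):
            self._accumulate(g.transpose(inv))

        return Tensor(out, req, (self,), bwd if req else None)

    # ---------------------------------------------------------- activations
    def relu(self):
        mask = self.data > 0
        req = self.requires_grad

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor(self.data * mask, req, (self,), bwd if req else None)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out = e / e.sum(axis=axis, keepdims=True)
        req = self.requires_grad

        def bwd(g):
            dot = (g * out).sum(axis=axis, keepdims=True)
            self._accumulate(out * (g - dot))

        return Tensor(out, req, (self,), bwd if req else None)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor(out, req, tuple(tensors), bwd if req else None)
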