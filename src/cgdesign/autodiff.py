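"""A compact reverse-mode automatic-differentiation engine over numpy arrays.

The network in this package is small (a few million parameters, graphs of a
few thousand edges), so a tape-based scalar-free engine over dense float32
arrays is sufficient and keeps the whole stack dependency-light and exactly
reproducible. Tensors record their parents and a backward closure; calling
:meth:`Tensor.backward` runs the tape in reverse topological order.

Only the primitives the model needs are provided: broadcast arithmetic,
matmul, exp/log/sqrt/power, GELU/ReLU, axis reductions, gather / segment-sum
(the graph aggregation pair), concatenation and reshape.
"""

from __future__ import annotations

import numpy as np

#: working precision of the engine; float32 keeps desk-scale training fast
DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_borrowed")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self._grad_borrowed = False
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd core --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=DTYPE)
        self._grad_borrowed = False
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(np.asarray(node.grad, dtype=DTYPE))

    def _accumulate(self, grad: np.ndarray) -> None:
        # the first contribution is borrowed by reference; a second
        # contribution allocates, so borrowed arrays are never mutated
        if self.grad is None:
            self.grad = grad
            self._grad_borrowed = True
        elif self._grad_borrowed:
            self.grad = self.grad + grad
            self._grad_borrowed = False
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None
        self._grad_borrowed = False

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data + other.data)
        out._parents = (self, other)

        def backward(grad):
            self._accumulate(_unbroadcast(grad, self.shape))
            other._accumulate(_unbroadcast(grad, other.shape))
        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data * other.data)
        out._parents = (self, other)

        def backward(grad):
            self._accumulate(_unbroadcast(grad * other.data, self.shape))
            other._accumulate(_unbroadcast(grad * self.data, other.shape))
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data / other.data)
        out._parents = (self, other)

        def backward(grad):
            self._accumulate(_unbroadcast(grad / other.data, self.shape))
            other._accumulate(_unbroadcast(
                -grad * self.data / (other.data ** 2), other.shape))
        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent)
        out._parents = (self,)

        def backward(grad):
            self._accumulate(grad * exponent * self.data ** (exponent - 1))
        out._backward = backward
        return out

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data @ other.data)
        out._parents = (self, other)

        def backward(grad):
            a, b = self.data, other.data
            self._accumulate(_unbroadcast(grad @ np.swapaxes(b, -1, -2),
                                          self.shape))
            other._accumulate(_unbroadcast(np.swapaxes(a, -1, -2) @ grad,
                                           other.shape))
        out._backward = backward
        return out

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data))
        out._parents = (self,)

        def backward(grad):
            self._accumulate(grad * out.data)
        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data))
        out._parents = (self,)

        def backward(grad):
            self._accumulate(grad / self.data)
        out._backward = backward
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data))
        out._parents = (self,)

        def backward(grad):
            self._accumulate(grad * 0.5 / out.data)
        out._backward = backward
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0))
        out._parents = (self,)

        def backward(grad):
            self._accumulate(grad * (self.data > 0))
        out._backward = backward
        return out

    def gelu(self):
        # tanh approximation; derivative computed in closed form
        c = np.float32(np.sqrt(2.0 / np.pi))
        x = self.data
        x2 = x * x
        inner = c * (x + np.float32(0.044715) * x2 * x)
        t = np.tanh(inner)
        out = Tensor(0.5 * x * (1.0 + t))
        out._parents = (self,)

        def backward(grad):
            dinner = c * (1.0 + np.float32(3 * 0.044715) * x2)
            deriv = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner
            self._accumulate(grad * deriv)
        out._backward = backward
        return out

    # -- reductions and shape -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        out._parents = (self,)

        def backward(grad):
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        count = (self.data.size if axis is None
                 else self.data.shape[axis])
        return self.sum(axis=axis, keepdims=keepdims) / float(count)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape))
        out._parents = (self,)

        def backward(grad):
            self._accumulate(grad.reshape(self.shape))
        out._backward = backward
        return out

    def gather(self, index: np.ndarray):
        """Row selection ``out[k] = self[index[k]]`` along axis 0."""
        index = np.asarray(index, dtype=int)
        out = Tensor(self.data[index])
        out._parents = (self,)

        def backward(grad):
            acc = np.zeros_like(self.data)
            np.add.at(acc, index, grad)
            self._accumulate(acc)
        out._backward = backward
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out._parents = tuple(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad):
        for t, g in zip(tensors, np.split(grad, splits, axis=axis)):
            t._accumulate(g)
    out._backward = backward
    return out


def segment_sum(x: Tensor, index: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets given by ``index``."""
    index = np.asarray(index, dtype=int)
    data = np.zeros((num_segments,) + x.data.shape[1:], dtype=DTYPE)
    np.add.at(data, index, x.data)
    out = Tensor(data)
    out._parents = (x,)

    def backward(grad):
        x._accumulate(grad[index])
    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stabilized softmax (the max shift is detached)."""
    shift = np.max(x.data, axis=axis, keepdims=True)
    z = (x - shift).exp()
    return z / z.sum(axis=axis, keepdims=True)


def segment_softmax(logits: Tensor, index: np.ndarray, num_segments: int,
                    ) -> Tensor:
    """Softmax of ``logits`` (E, 1) normalized within segments of ``index``."""
    index = np.asarray(index, dtype=int)
    shift = np.full((num_segments, 1), -np.inf, dtype=DTYPE)
    np.maximum.at(shift, index, logits.data)
    z = (logits - shift[index]).exp()
    denom = segment_sum(z, index, num_segments)
    return z / denom.gather(index)
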