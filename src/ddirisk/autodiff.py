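"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations needed by the graph layers in this package:
broadcasting arithmetic, matmul, elementwise nonlinearities, reductions,
row gathering and segment reductions (the sparse aggregation primitives of
message passing), concatenation and reshaping.  Gradients are accumulated
into ``Tensor.grad`` by :meth:`Tensor.backward` via a topological sweep.

Design constraints:

- arrays are left in whatever float dtype the caller provides (float64 for
  gradient checks, float32 for training speed);
- no in-place mutation of ``data`` after construction;
- every op registers a closure computing vector-Jacobian products only for
  parents with ``requires_grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "AdamW"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self.grad = None
        self._prev = tuple(_prev)
        self._backward = _backward

    # ------------------------------------------------------------------ utils
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=g.dtype)
        self.grad = self.grad + g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                         self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                          other.data.shape))

        out._backward = backward
        return out

    # ---------------------------------------------------------- elementwise
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out._backward = backward
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data),
                     _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * np.where(self.data > 0, 1.0, slope))

        out._backward = backward
        return out

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * val)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = backward
        return out

    def sqrt(self):
        return self ** 0.5

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        val = self.data.max(axis=axis, keepdims=True)
        out = Tensor(val if keepdims else val.squeeze(axis), _prev=(self,))
        mask = (self.data == val)

        def backward(g):
            if not self.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            counts = mask.sum(axis=axis, keepdims=True)
            self._accum(mask * gg / counts)  # split subgradient over ties

        out._backward = backward
        return out

    # ------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.data.transpose(*axes) if axes else self.data.T,
                     _prev=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axes:
                inv = np.argsort(axes)
                self._accum(g.transpose(*inv))
            else:
                self._accum(g.T)

        out._backward = backward
        return out

    @property
    def T(self):
        return self.transpose()

    # ---------------------------------------------------- gather and segment
    def gather_rows(self, index: np.ndarray):
        """Select rows ``self[index]``; gradient scatter-adds back."""
        index = np.asarray(index, dtype=np.intp)
        out = Tensor(self.data[index], _prev=(self,))

        def backward(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data, dtype=g.dtype)
                np.add.at(acc, index, g)
                self._accum(acc)

        out._backward = backward
        return out

    def segment_sum(self, index: np.ndarray, n_segments: int):
        """Row-wise scatter-add: ``out[k] = sum over rows i with index[i]==k``."""
        index = np.asarray(index, dtype=np.intp)
        val = np.zeros((n_segments,) + self.data.shape[1:], dtype=self.data.dtype)
        np.add.at(val, index, self.data)
        out = Tensor(val, _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g[index])

        out._backward = backward
        return out

    def segment_max(self, index: np.ndarray, n_segments: int):
        """Row-wise scatter-max; empty segments yield 0 and receive no gradient."""
        index = np.asarray(index, dtype=np.intp)
        val = np.full((n_segments,) + self.data.shape[1:], -np.inf,
                      dtype=self.data.dtype)
        np.maximum.at(val, index, self.data)
        empty = ~np.isfinite(val)
        val = np.where(empty, 0.0, val)
        out = Tensor(val, _prev=(self,))
        mask = (self.data == val[index]) & ~empty[index]

        def backward(g):
            if not self.requires_grad:
                return
            counts = np.zeros_like(val)
            np.add.at(counts, index, mask.astype(val.dtype))
            counts = np.maximum(counts, 1.0)
            self._accum(mask * (g / counts)[index])

        out._backward = backward
        return out

    # --------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs here can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar output")
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate along ``axis``; gradient splits back by slice."""
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = backward
    return out


class AdamW:
    """AdamW with decoupled weight decay.

    Weight decay multiplies parameters by ``(1 - lr*wd)`` each step,
    independently of the adaptive gradient term.
    """

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self._m[k] = self.b1 * self._m[k] + (1.0 - self.b1) * g
            self._v[k] = self.b2 * self._v[k] + (1.0 - self.b2) * g * g
            mhat = self._m[k] / b1t
            vhat = self._v[k] / b2t
            p.data = p.data * (1.0 - self.lr * self.weight_decay) \
                - self.lr * mhat / (np.sqrt(vhat) + self.eps)
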