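"""Compact vectorized reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the point network needs: broadcasting
arithmetic, matrix products over the last two axes, gather/scatter by integer
index, axis reductions (sum / mean / max), elementwise nonlinearities and
concatenation.  Gradients are accumulated by reverse topological sweep.

Every op is gradient-checked against central finite differences in the test
suite; the engine is deliberately minimal rather than general.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "Adam", "DEFAULT_DTYPE"]

#: dtype for activations and parameters; float32 keeps the large
#: (points × neighbors × width) intermediates memory-bandwidth friendly.
DEFAULT_DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
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
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str = ""):
        self.data = np.asarray(data, dtype=DEFAULT_DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape))
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse sweep from this tensor (default seed: ones)."""
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = (np.ones_like(self.data) if grad is None
                     else np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.data.shape))

        return Tensor(self.data / other.data, parents=(self, other), backward=bwd)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, k: float):
        k = float(k)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * k * self.data ** (k - 1.0))

        return Tensor(self.data ** k, parents=(self,), backward=bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        """(..., m, d) @ (d, h); weight `other` must be 2-D."""
        other = self._lift(other)
        a, w = self.data, other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ w.T)
            if other.requires_grad:
                other._accum(a.reshape(-1, a.shape[-1]).T @ g.reshape(-1, g.shape[-1]))

        return Tensor(a @ w, parents=(self, other), backward=bwd)

    __matmul__ = matmul

    def affine(self, weight: "Tensor", bias: "Tensor") -> "Tensor":
        """Fused x @ W + b over the last axis (one intermediate array)."""
        a, w = self.data, weight.data
        out = a @ w
        out += bias.data

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ w.T)
            if weight.requires_grad:
                weight._accum(a.reshape(-1, a.shape[-1]).T
                              @ g.reshape(-1, g.shape[-1]))
            if bias.requires_grad:
                bias._accum(g.reshape(-1, g.shape[-1]).sum(axis=0))

        return Tensor(out, parents=(self, weight, bias), backward=bwd)

    # ----------------------------------------------------------- nonlinearity
    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(np.clip(self.data, lo, hi), parents=(self,), backward=bwd)

    def minimum(self, other: "Tensor"):
        other = self._lift(other)
        take_self = self.data <= other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * take_self, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~take_self, other.data.shape))

        return Tensor(np.minimum(self.data, other.data), parents=(self, other),
                      backward=bwd)

    def maximum(self, other: "Tensor"):
        other = self._lift(other)
        take_self = self.data >= other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * take_self, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~take_self, other.data.shape))

        return Tensor(np.maximum(self.data, other.data), parents=(self, other),
                      backward=bwd)

    # -------------------------------------------------------------- shape ops
    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    def gather(self, idx: np.ndarray):
        """Index rows along axis 0; idx may be any integer ndarray shape."""
        idx = np.asarray(idx, dtype=np.intp)

        def bwd(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx.reshape(-1),
                          g.reshape(-1, *self.data.shape[1:]))
                self._accum(acc)

        return Tensor(self.data[idx], parents=(self,), backward=bwd)

    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        """Max-reduce one axis; gradient flows to the (first) argmax only."""
        arg = np.expand_dims(self.data.argmax(axis=axis), axis)

        def bwd(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.put_along_axis(acc, arg, np.expand_dims(g, axis), axis)
                self._accum(acc)

        return Tensor(np.take_along_axis(self.data, arg, axis).squeeze(axis),
                      parents=(self,), backward=bwd)


def concat(tensors: list, axis: int = -1) -> Tensor:
    """Concatenate along an axis, splitting the gradient back."""
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bwd)


class Adam:
    """Adam with decoupled weight decay applied to weight matrices only."""

    def __init__(self, params: dict, lr: float = 5e-4, weight_decay: float = 0.01,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

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
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            update = (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            if self.weight_decay and p.data.ndim >= 2:  # decay weights, not biases
                update = update + self.weight_decay * p.data
            p.data -= self.lr * update
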