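"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the dense operations the node-regression models need:
matmul, broadcast add/mul/sub, ReLU and leaky ReLU, exp, sum/mean, and
elementwise power. Gradients of broadcast operands are unbroadcast by
summation. Deliberately tiny: full-batch training on graphs of a few hundred
nodes does not need anything more.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "parameter", "relu", "leaky_relu", "matmul"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph walk ---------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    @property
    def _needs_grad(self) -> bool:
        # constant leaves need no gradient; skipping them avoids the large
        # matmul of e.g. the propagation operator's would-be gradient
        return self.requires_grad or self._backward is not None

    def _accumulate(self, grad) -> None:
        if not self._needs_grad:
            return
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- ops ----------------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self._accumulate(g)
            other._accumulate(g)

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __sub__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self._accumulate(g)
            other._accumulate(-g)

        return Tensor(self.data - other.data, parents=(self, other), backward=bwd)

    def __mul__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __truediv__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / (other.data**2))

        return Tensor(self.data / other.data, parents=(self, other), backward=bwd)

    def __pow__(self, exponent: float):
        def bwd(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(self.data**exponent, parents=(self,), backward=bwd)

    def __matmul__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            if self._needs_grad:
                self._accumulate(g @ np.swapaxes(other.data, -1, -2))
            if other._needs_grad:
                other._accumulate(np.swapaxes(self.data, -1, -2) @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bwd)

    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape))

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            parents=(self,),
            backward=bwd,
        )

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def reshape(self, *shape):
        def bwd(g):
            self._accumulate(g.reshape(self.data.shape))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    def expand_dims(self, axis: int):
        def bwd(g):
            self._accumulate(np.squeeze(g, axis=axis))

        return Tensor(np.expand_dims(self.data, axis), parents=(self,), backward=bwd)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    return Tensor(x)


def parameter(x) -> Tensor:
    return Tensor(np.array(x, dtype=float), requires_grad=True)


def relu(x: Tensor) -> Tensor:
    mask = (x.data > 0).astype(float)

    def bwd(g):
        x._accumulate(g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=bwd)


def leaky_relu(x: Tensor, alpha: float = 0.2) -> Tensor:
    slope = np.where(x.data > 0, 1.0, alpha)

    def bwd(g):
        x._accumulate(g * slope)

    return Tensor(x.data * slope, parents=(x,), backward=bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return _as_tensor(a) @ _as_tensor(b)


class Adam:
    """Adaptive-moment gradient descent over a dict of parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-2,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * p.grad
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * p.grad**2
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
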