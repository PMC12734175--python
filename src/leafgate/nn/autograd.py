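"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: each :class:`Tensor` wraps an
ndarray and remembers how to push a cotangent back to its parents.
Only the operations the leaf-disease network needs are provided; every
operation's gradient is validated against central finite differences in
the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward_fn: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward_fn

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # ------------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (a scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a cotangent requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS post-order; recursion depth is unbounded for deep nets
        visiting: list[tuple[Tensor, bool]] = [(self, False)]
        while visiting:
            node, processed = visiting.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visiting.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    visiting.append((p, False))
        del stack_
        self.accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _binary(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        other = Tensor._coerce(other)
        out_data = fwd(self.data, other.data)
        req = self.requires_grad or other.requires_grad
        out = Tensor(out_data, requires_grad=req, parents=(self, other))

        def _backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self.accumulate(_unbroadcast(bwd_self(g), self.shape))
            if other.requires_grad:
                other.accumulate(_unbroadcast(bwd_other(g), other.shape))

        out._backward = _backward if req else None
        return out

    def __add__(self, other):
        return self._binary(other, np.add, lambda g: g, lambda g: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, np.subtract, lambda g: g, lambda g: -g)

    def __rsub__(self, other):
        return Tensor._coerce(other).__sub__(self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        return self._binary(
            other, np.multiply, lambda g: g * other.data, lambda g: g * self.data
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        return self._binary(
            other,
            np.divide,
            lambda g: g / other.data,
            lambda g: -g * self.data / (other.data**2),
        )

    def __neg__(self):
        return self * -1.0

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], requires_grad=self.requires_grad, parents=(self,))

        def _backward(g: np.ndarray) -> None:
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self.accumulate(full)

        out._backward = _backward if self.requires_grad else None
        return out

    # -- linear algebra -------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._coerce(other)
        out_data = self.data @ other.data
        req = self.requires_grad or other.requires_grad
        out = Tensor(out_data, requires_grad=req, parents=(self, other))

        def _backward(g: np.ndarray) -> None:
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self.accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other.accumulate(_unbroadcast(gb, other.shape))

        out._backward = _backward if req else None
        return out

    __matmul__ = matmul

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(
            self.data.reshape(shape), requires_grad=self.requires_grad, parents=(self,)
        )
        src_shape = self.shape
        if self.requires_grad:
            out._backward = lambda g: self.accumulate(g.reshape(src_shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(
            self.data.transpose(axes), requires_grad=self.requires_grad, parents=(self,)
        )
        if self.requires_grad:
            out._backward = lambda g: self.accumulate(g.transpose(inv))
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        out = Tensor(out_data, requires_grad=self.requires_grad, parents=(self,))

        def _backward(g: np.ndarray) -> None:
            if axis is None:
                self.accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self.accumulate(np.broadcast_to(g, self.shape).copy())

        if self.requires_grad:
            out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities ------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(
            self.data * mask, requires_grad=self.requires_grad, parents=(self,)
        )
        if self.requires_grad:
            out._backward = lambda g: self.accumulate(g * mask)
        return out

    def gelu(self) -> "Tensor":
        """Exact (erf-based) Gaussian error linear unit."""
        from scipy.special import erf

        x = self.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = Tensor(x * cdf, requires_grad=self.requires_grad, parents=(self,))
        if self.requires_grad:
            pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
            deriv = cdf + x * pdf
            out._backward = lambda g: self.accumulate(g * deriv)
        return out

    def __pow__(self, exponent: float) -> "Tensor":
        """Elementwise power with a scalar exponent (base clamped at 0)."""
        x = np.maximum(self.data, 0.0)
        out = Tensor(x**exponent, requires_grad=self.requires_grad, parents=(self,))
        if self.requires_grad:
            # derivative exponent*x^(exponent-1); clamp avoids inf at x=0
            deriv = exponent * np.maximum(x, 1e-12) ** (exponent - 1.0)
            out._backward = lambda g: self.accumulate(g * deriv)
        return out

    def log(self, eps: float = 0.0) -> "Tensor":
        x = self.data if eps == 0.0 else np.maximum(self.data, eps)
        out = Tensor(np.log(x), requires_grad=self.requires_grad, parents=(self,))
        if self.requires_grad:
            out._backward = lambda g: self.accumulate(g / x)
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, requires_grad=self.requires_grad, parents=(self,))
        if self.requires_grad:
            out._backward = lambda g: self.accumulate(g * e)
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, requires_grad=self.requires_grad, parents=(self,))

        def _backward(g: np.ndarray) -> None:
            dot = (g * s).sum(axis=axis, keepdims=True)
            self.accumulate(s * (g - dot))

        if self.requires_grad:
            out._backward = _backward
        return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(out_data, requires_grad=req, parents=tuple(tensors))

    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.accumulate(g[tuple(idx)])

    out._backward = _backward if req else None
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(out_data, requires_grad=req, parents=tuple(tensors))

    def _backward(g: np.ndarray) -> None:
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t.accumulate(np.take(g, i, axis=axis))

    out._backward = _backward if req else None
    return out
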