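"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations that
produced it on a tape; :meth:`Tensor.backward` walks the tape in reverse
topological order and accumulates gradients.  The operation set is exactly
what the recurrent generator and the synergy predictor need: elementwise
arithmetic with broadcasting, matmul, tanh/sigmoid/relu, softmax,
concatenation, slicing, reductions, embedding lookup and a fused
softmax-cross-entropy.  Gradients are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "embedding", "softmax_cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs from long sequences overflow recursion
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accum(g)
            other._accum(g)

        return Tensor(self.data + other.data, _parents=(self, other), _backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor(self.data * other.data, _parents=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("division only by python scalars")
        return self * (1.0 / scalar)

    def __matmul__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accum(g @ np.swapaxes(other.data, -1, -2))
            other._accum(np.swapaxes(self.data, -1, -2) @ g)

        return Tensor(self.data @ other.data, _parents=(self, other), _backward=bwd)

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        return Tensor(self.data[idx], _parents=(self,), _backward=bwd)

    # ------------------------------------------------------------ nonlinearity
    def tanh(self):
        out = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - out * out))

        return Tensor(out, _parents=(self,), _backward=bwd)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bwd(g):
            self._accum(g * out * (1.0 - out))

        return Tensor(out, _parents=(self,), _backward=bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=bwd)

    def exp(self):
        out = np.exp(self.data)

        def bwd(g):
            self._accum(g * out)

        return Tensor(out, _parents=(self,), _backward=bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bwd)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            dot = (g * out).sum(axis=axis, keepdims=True)
            self._accum(out * (g - dot))

        return Tensor(out, _parents=(self,), _backward=bwd)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor(out, _parents=(self,), _backward=bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def abs(self):
        sign = np.sign(self.data)

        def bwd(g):
            self._accum(g * sign)

        return Tensor(np.abs(self.data), _parents=(self,), _backward=bwd)

    def square(self):
        return self * self

    def reshape(self, *shape):
        def bwd(g):
            self._accum(g.reshape(self.data.shape))

        return Tensor(self.data.reshape(*shape), _parents=(self,), _backward=bwd)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=bwd,
    )


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup ``weight[idx]`` with scatter-add gradient."""
    idx = np.asarray(idx)

    def bwd(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, idx, g)
        weight._accum(full)

    return Tensor(weight.data[idx], _parents=(weight,), _backward=bwd)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
    """Mean cross-entropy of integer ``targets`` under ``softmax(logits)``.

    ``logits``: (N, V); ``targets``: (N,) ints; ``mask``: optional (N,) 0/1
    weights (padding positions get 0).  The softmax and log are fused so the
    backward pass is the numerically stable ``p - onehot``.
    """
    targets = np.asarray(targets)
    if mask is None:
        mask = np.ones(len(targets))
    mask = np.asarray(mask, dtype=np.float64)
    denom = max(mask.sum(), 1.0)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    nll = -(logp[np.arange(len(targets)), targets] * mask).sum() / denom

    def bwd(g):
        p = np.exp(logp)
        p[np.arange(len(targets)), targets] -= 1.0
        logits._accum(g * p * (mask / denom)[:, None])

    return Tensor(nll, _parents=(logits,), _backward=bwd)
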