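"""Minimal reverse-mode autodiff on numpy arrays.

Only the operations needed by the sequence classifiers are provided:
elementwise arithmetic, matmul, 1-D (dilated) convolution, pooling,
activations, concatenation and reductions.  Tensors form a DAG; calling
:meth:`Tensor.backward` on a scalar runs reverse-mode accumulation in
topological order.

Fused recurrent cells (LSTM/GRU) live in :mod:`m6amstack.nn.recurrent`;
they register themselves as single nodes in this graph.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv1d",
    "max_pool1d",
    "avg_pool1d",
    "global_avg_pool",
    "dropout",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, _parents=(), name: str = ""):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = _parents
        self.name = name

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = _backward
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _backward
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                              self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                               other.data.shape))

        out._backward = _backward
        return out

    # -- shape ---------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        out._backward = _backward
        return out

    # -- activations ---------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = _backward
        return out

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        neg_part = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        val = np.where(pos, self.data, neg_part)
        out = Tensor(val, self.requires_grad, (self,))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(g * np.where(pos, 1.0, neg_part + alpha))

        out._backward = _backward
        return out

    def sigmoid(self):
        with np.errstate(over="ignore"):  # saturates to the correct limit
            val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, self.requires_grad, (self,))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(g * val * (1.0 - val))

        out._backward = _backward
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, self.requires_grad, (self,))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - val * val))

        out._backward = _backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = _backward
        return out

    # -- reductions ----------------------------------------------------
    def sum(self):
        out = Tensor(self.data.sum(), self.requires_grad, (self,))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _backward
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), self.requires_grad, (self,))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(np.full(self.data.shape, g / n, dtype=self.data.dtype))

        out._backward = _backward
        return out

    def mean_axis(self, axis: int):
        n = self.data.shape[axis]
        out = Tensor(self.data.mean(axis=axis), self.requires_grad, (self,))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(np.repeat(np.expand_dims(g / n, axis), n, axis=axis))

        out._backward = _backward
        return out

    # -- autodiff ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion depth
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


# ---------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, req, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    out._backward = _backward
    return out


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           dilation: int = 1, padding: str = "same") -> Tensor:
    """1-D convolution over (batch, length, channels) input.

    weight has shape (K, C_in, C_out).  With ``padding="same"`` the output
    keeps the input length for any dilation; taps are spaced ``dilation``
    positions apart so rate 1 is an ordinary convolution.
    """
    B, L, Cin = x.data.shape
    K, Cin_w, Cout = weight.data.shape
    if Cin_w != Cin:
        raise ValueError(f"channel mismatch: input {Cin}, weight {Cin_w}")
    span = dilation * (K - 1)
    if padding == "same":
        left = span // 2
        right = span - left
        Lout = L
    elif padding == "valid":
        left = right = 0
        Lout = L - span
        if Lout <= 0:
            raise ValueError("window shorter than dilated kernel span")
    else:
        raise ValueError(f"unknown padding {padding!r}")

    xp = np.pad(x.data, ((0, 0), (left, right), (0, 0))) if (left or right) else x.data
    y = np.zeros((B, Lout, Cout), dtype=x.data.dtype)
    for t in range(K):
        y += xp[:, t * dilation:t * dilation + Lout, :] @ weight.data[t]
    if bias is not None:
        y += bias.data

    parents = (x, weight) if bias is None else (x, weight, bias)
    req = any(p.requires_grad for p in parents)
    out = Tensor(y, req, parents)

    def _backward(g):
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for t in range(K):
                dxp[:, t * dilation:t * dilation + Lout, :] += g @ weight.data[t].T
            dx = dxp[:, left:left + L, :] if (left or right) else dxp
            x._accumulate(dx)
        if weight.requires_grad:
            dW = np.empty_like(weight.data)
            gf = g.reshape(-1, Cout)
            for t in range(K):
                xs = xp[:, t * dilation:t * dilation + Lout, :].reshape(-1, Cin)
                dW[t] = xs.T @ gf
            weight._accumulate(dW)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 1)))

    out._backward = _backward
    return out


def max_pool1d(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping max pooling along the length axis (trailing remainder dropped)."""
    B, L, C = x.data.shape
    Lout = L // pool
    trimmed = x.data[:, :Lout * pool, :].reshape(B, Lout, pool, C)
    idx = trimmed.argmax(axis=2)
    val = np.take_along_axis(trimmed, idx[:, :, None, :], axis=2)[:, :, 0, :]
    out = Tensor(val, x.requires_grad, (x,))

    def _backward(g):
        if x.requires_grad:
            dtr = np.zeros_like(trimmed)
            np.put_along_axis(dtr, idx[:, :, None, :], g[:, :, None, :], axis=2)
            dx = np.zeros_like(x.data)
            dx[:, :Lout * pool, :] = dtr.reshape(B, Lout * pool, C)
            x._accumulate(dx)

    out._backward = _backward
    return out


def avg_pool1d(x: Tensor, pool: int) -> Tensor:
    B, L, C = x.data.shape
    Lout = L // pool
    trimmed = x.data[:, :Lout * pool, :].reshape(B, Lout, pool, C)
    out = Tensor(trimmed.mean(axis=2), x.requires_grad, (x,))

    def _backward(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            dx[:, :Lout * pool, :] = np.repeat(g / pool, pool, axis=1)
            x._accumulate(dx)

    out._backward = _backward
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over the length axis: (B, L, C) -> (B, C)."""
    return x.mean_axis(1)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep).astype(x.data.dtype) / keep
    out = Tensor(x.data * mask, x.requires_grad, (x,))

    def _backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = _backward
    return out
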