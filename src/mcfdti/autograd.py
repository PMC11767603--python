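"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model in this package is small enough that a compact tape-based engine is
sufficient: a :class:`Tensor` wraps an ``ndarray``, records the operation that
produced it, and :meth:`Tensor.backward` walks the tape in reverse topological
order accumulating gradients. Only the operations the architecture needs are
implemented (dense/conv/attention arithmetic, pointwise nonlinearities,
reductions, shape ops, embedding lookup).

Float32 is the working precision; float64 inputs are preserved, which the test
suite uses for numerical gradient checks.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "embedding", "Adam"]


def _as_float(data) -> np.ndarray:
    arr = np.asarray(data)
    if arr.dtype not in (np.float32, np.float64):
        arr = arr.astype(np.float32)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus the bookkeeping needed for reverse-mode differentiation."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False):
        self.data: np.ndarray = _as_float(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()
        self._grad_owned = False

    # -- construction -----------------------------------------------------
    @classmethod
    def _make(cls, data: np.ndarray, prev: Sequence["Tensor"],
              backward: Callable[[], None]) -> "Tensor":
        out = cls(data)
        parents = tuple(p for p in prev if p.requires_grad or p._prev)
        if parents:
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    # -- properties -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accum(self, grad: np.ndarray) -> None:
        # first contribution is stored by reference; a second contribution
        # allocates, so upstream buffers are never mutated in place
        if self.grad is None:
            self.grad = grad
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += grad
        else:
            self.grad = self.grad + grad
            self._grad_owned = True

    def _coerce(self, other) -> "Tensor":
        """Wrap scalars/arrays in a constant Tensor matching our dtype, so
        python-float constants never upcast a float32 graph to float64."""
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward() -> None:
            g = out.grad
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward() -> None:
            self._accum(-out.grad)

        out = Tensor._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return self._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward() -> None:
            g = out.grad
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * self._coerce(other).pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out_data = self.data ** exponent

        def backward() -> None:
            self._accum(out.grad * exponent * self.data ** (exponent - 1.0))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def __matmul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        # matmul operands are arrays, never scalars; no dtype coercion needed
        out_data = np.matmul(self.data, other.data)

        def backward() -> None:
            g = out.grad
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accum(_unbroadcast(ga, self.shape))
            other._accum(_unbroadcast(gb, other.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    # -- pointwise nonlinearities ----------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward() -> None:
            self._accum(out.grad * mask)

        out = Tensor._make(np.where(mask, self.data, 0.0), (self,), backward)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward() -> None:
            self._accum(out.grad * s * (1.0 - s))

        out = Tensor._make(s, (self,), backward)
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)

        def backward() -> None:
            self._accum(out.grad * e)

        out = Tensor._make(e, (self,), backward)
        return out

    def log(self) -> "Tensor":
        def backward() -> None:
            self._accum(out.grad / self.data)

        out = Tensor._make(np.log(self.data), (self,), backward)
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward() -> None:
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out = Tensor._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max along one axis; gradient flows to the (first) arg-max entry."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        idx = np.expand_dims(self.data.argmax(axis=axis), axis)

        def backward() -> None:
            g = out.grad if keepdims else np.expand_dims(out.grad, axis)
            gx = np.zeros_like(self.data)
            np.put_along_axis(gx, idx, g, axis=axis)
            self._accum(gx)

        out = Tensor._make(out_data, (self,), backward)
        return out

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def backward() -> None:
            self._accum(out.grad.reshape(orig))

        out = Tensor._make(self.data.reshape(shape), (self,), backward)
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        def backward() -> None:
            self._accum(out.grad.swapaxes(a, b))

        out = Tensor._make(self.data.swapaxes(a, b), (self,), backward)
        return out

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        inv = np.argsort(axes)

        def backward() -> None:
            self._accum(out.grad.transpose(inv))

        out = Tensor._make(self.data.transpose(axes), (self,), backward)
        return out

    def __getitem__(self, key) -> "Tensor":
        def backward() -> None:
            gx = np.zeros_like(self.data)
            gx[key] = out.grad
            self._accum(gx)

        out = Tensor._make(self.data[key], (self,), backward)
        return out

    # -- composite helpers ------------------------------------------------
    def softmax(self, axis: int = -1) -> "Tensor":
        """Numerically stable softmax composed from primitive ops."""
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- backprop ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        self._grad_owned = True
        for node in reversed(topo):
            if node._backward is None:
                continue  # leaf: keep its accumulated gradient
            if node.grad is not None:
                node._backward()
            # release the tape eagerly: the closure in _backward references
            # the node itself (a cycle), so without this the graph would wait
            # for the generational GC while holding every intermediate array
            node._backward = None
            node._prev = ()
            if node is not self:
                node.grad = None


# ---------------------------------------------------------------------------
# free functions


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward() -> None:
        pieces = np.split(out.grad, splits, axis=axis)
        for t, g in zip(tensors, pieces):
            t._accum(g)

    out = Tensor._make(out_data, tensors, backward)
    return out


def embedding(indices: np.ndarray, table: Tensor) -> Tensor:
    """Row lookup ``table[indices]`` with scatter-add gradient."""
    indices = np.asarray(indices)
    if indices.size and (indices.min() < 0 or indices.max() >= table.shape[0]):
        raise IndexError(
            f"token index out of range for embedding table of size {table.shape[0]}")
    out_data = table.data[indices]

    def backward() -> None:
        gt = np.zeros_like(table.data)
        np.add.at(gt, indices.reshape(-1), out.grad.reshape(-1, table.shape[1]))
        table._accum(gt)

    out = Tensor._make(out_data, (table,), backward)
    return out


def conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """1-D convolution along the time axis with 'same' padding, stride 1.

    ``x`` is (B, T, C_in), ``weight`` is (K, C_in, C_out), ``bias`` is (C_out,).
    Implemented as im2col + matmul so BLAS does the heavy lifting.
    """
    B, T, Cin = x.shape
    K, wCin, Cout = weight.shape
    if Cin != wCin:
        raise ValueError(f"channel mismatch: input has {Cin}, kernel expects {wCin}")
    pad_l = (K - 1) // 2
    pad_r = K // 2
    xp = np.zeros((B, T + pad_l + pad_r, Cin), dtype=x.data.dtype)
    xp[:, pad_l:pad_l + T] = x.data
    # (B, T, Cin, K) sliding windows -> flat (B*T, K*Cin) for one big GEMM
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)
    col = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B * T, K * Cin)
    w2 = weight.data.reshape(K * Cin, Cout)
    out_data = (col @ w2 + bias.data).reshape(B, T, Cout)

    def backward() -> None:
        g = out.grad.reshape(B * T, Cout)
        weight._accum((col.T @ g).reshape(K, Cin, Cout))
        bias._accum(g.sum(axis=0))
        if x.requires_grad or x._prev:
            gcol = (g @ w2.T).reshape(B, T, K, Cin)
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, k:k + T] += gcol[:, :, k]
            x._accum(gxp[:, pad_l:pad_l + T])

    out = Tensor._make(out_data, (x, weight, bias), backward)
    return out


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
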