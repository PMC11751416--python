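"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This engine exists to support three needs of the package with one mechanism:
training the 1-D convolutional survival encoder and the temporal
convolutional network, verifying the censoring-aware loss gradients against
finite differences, and computing input-gradient saliency maps. It is a
deliberately small tape-based design: each operation records its parents and
a closure that accumulates gradients; :meth:`Tensor.backward` walks the tape
in reverse topological order.

Only the operations the package's models need are implemented. Broadcasting
follows NumPy semantics; gradients of broadcast operands are summed back to
the operand's shape.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
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
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------
    @classmethod
    def _from_op(cls, data, parents: Sequence["Tensor"],
                 backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = cls(data)
        parents = tuple(p for p in parents if p.requires_grad)
        if parents:
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (scalar unless `grad` is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=self.data.dtype)

        # topological order via iterative DFS
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        self._accum(grad)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _coerce(self, other) -> "Tensor":
        """Wrap a scalar/array operand, matching this tensor's float dtype.

        Python scalars would otherwise promote a float32 graph to float64.
        """
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        if (arr.dtype != self.data.dtype and arr.dtype.kind == "f"
                and self.data.dtype.kind == "f"):
            arr = arr.astype(self.data.dtype)
        return Tensor(arr)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ g)

        return Tensor._from_op(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            self._accum(g * mask)

        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self):
        from scipy.special import expit   # numerically stable both tails

        out_data = expit(self.data)

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Maximum along one axis; ties send the gradient to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis),
                                      axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            gx = np.zeros_like(self.data)
            np.put_along_axis(gx, np.expand_dims(idx, axis), g, axis=axis)
            self._accum(gx)

        return Tensor._from_op(out_data, (self,), backward)

    def cumsum(self, axis: int):
        out_data = np.cumsum(self.data, axis=axis)

        def backward(g):
            rev = np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis)
            self._accum(rev)

        return Tensor._from_op(out_data, (self,), backward)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            self._accum(g.reshape(orig))

        return Tensor._from_op(out_data, (self,), backward)

    def transpose(self, *axes):
        out_data = self.data.transpose(*axes)
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(*inv))

        return Tensor._from_op(out_data, (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, key, g)
            self._accum(gx)

        return Tensor._from_op(out_data, (self,), backward)

    # -- 1-D convolution ------------------------------------------------------
    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int | tuple[int, int] = 0,
               dilation: int = 1):
        """Cross-correlation along the last axis.

        Input shape (N, Cin, L); weight (Cout, Cin, K); output (N, Cout, Lout).
        `padding` may be an int (symmetric) or a (left, right) pair, which the
        causal convolutions of the TCN use for left-only padding.
        """
        x = self.data
        w = weight.data
        n, cin, length = x.shape
        cout, cin_w, k = w.shape
        if cin != cin_w:
            raise ValueError(f"channel mismatch: input {cin}, weight {cin_w}")
        pl, pr = (padding, padding) if isinstance(padding, int) else padding
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr))) if (pl or pr) else x
        lp = xp.shape[-1]
        span = (k - 1) * dilation + 1
        lout = (lp - span) // stride + 1
        if lout < 1:
            raise ValueError("convolution output would be empty")
        idx = np.arange(lout)[:, None] * stride + np.arange(k)[None, :] * dilation
        cols = xp[:, :, idx]                       # (N, Cin, Lout, K)
        colmat = cols.transpose(0, 2, 1, 3).reshape(n * lout, cin * k)
        wmat = w.reshape(cout, cin * k)
        out = (colmat @ wmat.T).reshape(n, lout, cout).transpose(0, 2, 1)
        if bias is not None:
            out = out + bias.data[:, None]

        def backward(g):                            # g: (N, Cout, Lout)
            gmat = g.transpose(0, 2, 1).reshape(n * lout, cout)
            if weight.requires_grad:
                gw = (gmat.T @ colmat).reshape(cout, cin, k)
                weight._accum(gw)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2)))
            if self.requires_grad:
                gcols = (gmat @ wmat).reshape(n, lout, cin, k).transpose(0, 2, 1, 3)
                gxp = np.zeros_like(xp)
                # per-tap scatter: for fixed k the strided positions are distinct
                for tap in range(k):
                    pos = idx[:, tap]
                    gxp[:, :, pos] += gcols[:, :, :, tap]
                gx = gxp[:, :, pl:lp - pr] if (pl or pr) else gxp
                self._accum(gx)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._from_op(out, parents, backward)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        flag = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.shape}, dtype={self.data.dtype}{flag})"


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along `axis` with gradient routing."""
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._from_op(out_data, tensors, backward)
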