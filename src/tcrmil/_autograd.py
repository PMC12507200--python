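"""Minimal reverse-mode automatic differentiation over numpy arrays.

The MIL network in :mod:`tcrmil.model` is small (a two-block 1-D CNN, one
transformer encoder layer and two linear heads) and is trained on modest
batch sizes, so a compact tape-based engine over numpy is sufficient.  Only
the operations the network needs are implemented: broadcast arithmetic,
(batched) matmul, ReLU/exp/log/sigmoid, reductions, reshape/transpose,
row gather/scatter, an im2col 1-D convolution and a numerically stable
binary cross-entropy on logits.

Gradient correctness is verified against central finite differences in the
test suite; every backward rule here is exact, not approximate.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "scaled_dot_attention", "batchnorm_train"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    """A numpy array plus the closure that propagates its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_shared")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None
        self._grad_shared = False

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _result(data: np.ndarray, parents: Sequence["Tensor"],
                backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._result(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return self._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._result(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data * other.data), other.shape)
                )

        return self._result(data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        data = self.data ** exponent

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return self._result(data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.multiply.outer(g, other.data) if g.ndim else g * other.data
                else:
                    ga = g @ np.swapaxes(other.data, -1, -2) if self.data.ndim > 1 else (
                        np.swapaxes(other.data, -1, -2) @ g
                    )
                self._accumulate(_unbroadcast(np.asarray(ga), self.shape))
            if other.requires_grad:
                if self.data.ndim == 1 and other.data.ndim == 2:
                    gb = np.multiply.outer(self.data, g)
                elif other.data.ndim == 1:
                    gb = np.swapaxes(self.data, -1, -2) @ g if self.data.ndim > 1 else self.data * g
                    gb = gb.reshape(other.shape) if gb.ndim > 1 else gb
                else:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(np.asarray(gb), other.shape))

        return self._result(data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def relu(self):
        mask = self.data > 0
        data = self.data * mask

        def backward(g):
            self._accumulate(g * mask)

        return self._result(data, (self,), backward)

    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * data)

        return self._result(data, (self,), backward)

    def log(self):
        data = np.log(self.data)

        def backward(g):
            self._accumulate(g / self.data)

        return self._result(data, (self,), backward)

    def sigmoid(self):
        data = _sigmoid(self.data)

        def backward(g):
            self._accumulate(g * data * (1.0 - data))

        return self._result(data, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return self._result(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max over one axis; gradient flows to the (first) argmax."""
        data = self.data.max(axis=axis, keepdims=keepdims)
        arg = self.data.argmax(axis=axis)

        def backward(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            out = np.zeros_like(self.data)
            np.put_along_axis(out, np.expand_dims(arg, axis), g, axis=axis)
            self._accumulate(out)

        return self._result(data, (self,), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        data = self.data.reshape(shape)

        def backward(g):
            self._accumulate(g.reshape(self.shape))

        return self._result(data, (self,), backward)

    def transpose(self, axes: Sequence[int]):
        data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return self._result(data, (self,), backward)

    def take_rows(self, index: np.ndarray):
        """Gather rows along axis 0 (index may repeat)."""
        data = self.data[index]

        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, index, g)
            self._accumulate(out)

        return self._result(data, (self,), backward)

    def scatter_rows(self, index: np.ndarray, n_rows: int):
        """Inverse of :meth:`take_rows`: place rows at `index` in a zero block."""
        data = np.zeros((n_rows,) + self.shape[1:], dtype=self.data.dtype)
        data[index] = self.data

        def backward(g):
            self._accumulate(g[index])

        return self._result(data, (self,), backward)

    # -- fused ops ------------------------------------------------------------

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            # d softmax: s * (g - sum(g*s))
            dot = (g * data).sum(axis=axis, keepdims=True)
            self._accumulate(data * (g - dot))

        return self._result(data, (self,), backward)

    def conv1d(self, weight: "Tensor", bias: "Tensor"):
        """1-D cross-correlation, stride 1, no padding.

        self: (N, C_in, L); weight: (C_out, C_in, k); bias: (C_out,)
        returns (N, C_out, L - k + 1).
        """
        x = self.data
        n, c_in, length = x.shape
        c_out, _, k = weight.shape
        l_out = length - k + 1
        # im2col: patches (N, L_out, C_in * k), contiguous for BLAS
        s0, s1, s2 = x.strides
        patches = np.lib.stride_tricks.as_strided(
            x, shape=(n, l_out, c_in, k), strides=(s0, s2, s1, s2)
        ).reshape(n, l_out, c_in * k)
        patches = np.ascontiguousarray(patches).reshape(n * l_out, c_in * k)
        w2 = weight.data.reshape(c_out, c_in * k)
        y = (patches @ w2.T).reshape(n, l_out, c_out) + bias.data
        data = np.ascontiguousarray(y.transpose(0, 2, 1))

        def backward(g):
            g2 = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(n * l_out, c_out)
            if bias.requires_grad:
                bias._accumulate(g2.sum(axis=0))
            if weight.requires_grad:
                weight._accumulate((g2.T @ patches).reshape(c_out, c_in, k))
            if self.requires_grad:
                gp = (g2 @ w2).reshape(n, l_out, c_in, k)
                gx = np.zeros_like(x)
                for t in range(k):
                    gx[:, :, t:t + l_out] += gp[:, :, :, t].transpose(0, 2, 1)
                self._accumulate(gx)

        return self._result(data, (self, weight, bias), backward)

    def bce_with_logits(self, targets: np.ndarray):
        """Elementwise max(z,0) - z*y + log(1 + exp(-|z|)); stable for large |z|."""
        z = self.data
        y = np.asarray(targets, dtype=z.dtype)
        data = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))

        def backward(g):
            self._accumulate(g * (_sigmoid(z) - y))

        return self._result(data, (self,), backward)

    # -- backward pass --------------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        # First contribution adopts the incoming buffer without copying; it
        # may alias another tensor's grad, so a second contribution switches
        # to out-of-place addition instead of mutating the shared array.
        if self.grad is None:
            g = np.asarray(g)
            if g.dtype != self.data.dtype or not g.flags.writeable:
                g = g.astype(self.data.dtype)
            self.grad = g
            self._grad_shared = True
        elif self._grad_shared:
            self.grad = self.grad + g
            self._grad_shared = False
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def as_tensor(value, dtype=None) -> Tensor:
    if isinstance(value, Tensor):
        return value
    return Tensor(np.asarray(value, dtype=dtype))


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor,
                         bias: np.ndarray) -> Tensor:
    """softmax(q k^T / sqrt(d_k) + bias) v, fused for memory efficiency.

    q, k, v: (..., K, d_k); bias: additive attention-logit offset broadcast
    over the score shape (..., K, K) (used for key masking; constant).
    """
    dk = q.shape[-1]
    scale = 1.0 / np.sqrt(dk)
    scores = (q.data @ np.swapaxes(k.data, -1, -2)) * scale + bias
    scores -= scores.max(axis=-1, keepdims=True)
    np.exp(scores, out=scores)
    scores /= scores.sum(axis=-1, keepdims=True)
    attn = scores
    data = attn @ v.data

    def backward(g):
        if v.requires_grad:
            v._accumulate(np.swapaxes(attn, -1, -2) @ g)
        if q.requires_grad or k.requires_grad:
            d_attn = g @ np.swapaxes(v.data, -1, -2)
            d_scores = attn * (d_attn - (d_attn * attn).sum(axis=-1, keepdims=True))
            if q.requires_grad:
                q._accumulate((d_scores @ k.data) * scale)
            if k.requires_grad:
                k._accumulate((np.swapaxes(d_scores, -1, -2) @ q.data) * scale)

    return Tensor._result(data, (q, k, v), backward)


def batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor,
                    eps: float) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Training-mode batch normalization over (N, C, L): per-channel
    statistics across N and L.  Returns (y, batch_mean, biased_batch_var)
    so the caller can maintain running estimates."""
    n = x.shape[0] * x.shape[2]
    mean = x.data.mean(axis=(0, 2))
    centered = x.data - mean[None, :, None]
    var = np.mean(centered * centered, axis=(0, 2))
    std_inv = 1.0 / np.sqrt(var + eps)
    xhat = centered * std_inv[None, :, None]
    data = xhat * gamma.data[None, :, None] + beta.data[None, :, None]

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2)))
        if x.requires_grad:
            dxhat = g * gamma.data[None, :, None]
            s1 = dxhat.sum(axis=(0, 2))[None, :, None]
            s2 = (dxhat * xhat).sum(axis=(0, 2))[None, :, None]
            x._accumulate((std_inv[None, :, None] / n)
                          * (n * dxhat - s1 - xhat * s2))

    return Tensor._result(data, (x, gamma, beta), backward), mean, var
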