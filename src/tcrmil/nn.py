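"""Neural-network layers used by the repertoire classifier.

Thin layer classes over :mod:`tcrmil._autograd`.  Weight matrices are drawn
from the zero-mean Xavier normal N(0, 2/(fan_in + fan_out)); biases start at
zero, batch-norm scale/shift at one/zero.  Dropout is inverted (survivors
scaled by 1/keep), so inference applies no rescaling.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, batchnorm_train, scaled_dot_attention


def xavier_normal(rng: np.random.Generator, shape: tuple[int, ...],
                  fan_in: int, fan_out: int, dtype) -> np.ndarray:
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=shape).astype(dtype)


def dropout(x: Tensor, rate: float, training: bool, rng: np.random.Generator) -> Tensor:
    """Inverted dropout: elementwise zeroing with prob `rate`, survivors / (1-rate)."""
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep).astype(x.data.dtype) / keep
    return x * mask


class Module:
    """Lightweight container: tracks parameters and named state arrays."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for _, value in sorted(vars(self).items()):
            if isinstance(value, Tensor) and value.requires_grad:
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
        return out

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, value in sorted(vars(self).items()):
            if isinstance(value, Tensor):
                out[prefix + name] = value.data.copy()
            elif isinstance(value, np.ndarray):
                out[prefix + name] = value.copy()
            elif isinstance(value, Module):
                out.update(value.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in sorted(vars(self).items()):
            if isinstance(value, Tensor):
                value.data = state[prefix + name].copy()
            elif isinstance(value, np.ndarray):
                setattr(self, name, state[prefix + name].copy())
            elif isinstance(value, Module):
                value.load_state_dict(state, prefix + name + ".")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        self.weight = Tensor(
            xavier_normal(rng, (n_in, n_out), n_in, n_out, dtype), requires_grad=True
        )
        self.bias = Tensor(np.zeros(n_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Stride-1, no-padding 1-D convolution (cross-correlation)."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32):
        fan_in, fan_out = c_in * kernel, c_out * kernel
        self.weight = Tensor(
            xavier_normal(rng, (c_out, c_in, kernel), fan_in, fan_out, dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias)


class BatchNorm1d(Module):
    """Per-channel batch normalization over (N, C, L) inputs.

    Training uses within-batch statistics (over N and L) and updates running
    estimates; inference normalizes with the running estimates.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            n = x.shape[0] * x.shape[2]
            y, mean, var = batchnorm_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mean).astype(self.running_mean.dtype)
            unbiased = var * (n / max(n - 1, 1))
            self.running_var = ((1 - m) * self.running_var
                                + m * unbiased).astype(self.running_var.dtype)
            return y
        mean = self.running_mean.reshape(1, -1, 1)
        std_inv = 1.0 / np.sqrt(self.running_var.reshape(1, -1, 1) + self.eps)
        xhat = (x - mean) * std_inv
        g = self.gamma.reshape(1, -1, 1)
        b = self.beta.reshape(1, -1, 1)
        return xhat * g + b


class LayerNorm(Module):
    """Normalization over the last axis with learned scale and shift."""

    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        centered = x - mean
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class MultiheadSelfAttention(Module):
    """Scaled dot-product self-attention over bag instances.

    Heads split d_model into h subspaces of size d_k = d_model / h; padded
    instances are excluded as keys by a large negative logit offset.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 dtype=np.float32):
        if d_model % n_heads != 0:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.w_q = Linear(d_model, d_model, rng, dtype)
        self.w_k = Linear(d_model, d_model, rng, dtype)
        self.w_v = Linear(d_model, d_model, rng, dtype)
        self.w_o = Linear(d_model, d_model, rng, dtype)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        """x: (B, K, d_model); mask: (B, K) booleans, True = real instance."""
        b, k, d = x.shape
        h, dk = self.n_heads, self.d_k

        def split(t: Tensor) -> Tensor:
            return t.reshape(b, k, h, dk).transpose((0, 2, 1, 3))  # (B, h, K, dk)

        q, kk, v = split(self.w_q(x)), split(self.w_k(x)), split(self.w_v(x))
        bias = np.where(mask, 0.0, -1e9).astype(x.data.dtype)[:, None, None, :]
        attn_out = scaled_dot_attention(q, kk, v, bias)
        out = attn_out.transpose((0, 2, 1, 3)).reshape(b, k, d)
        return self.w_o(out)


class TransformerEncoderLayer(Module):
    """Post-norm encoder block: attention and position-wise FFN, each with
    residual connection and layer normalization."""

    def __init__(self, d_model: int, n_heads: int, ffn_dim: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.attn = MultiheadSelfAttention(d_model, n_heads, rng, dtype)
        self.norm1 = LayerNorm(d_model, dtype=dtype)
        self.ffn1 = Linear(d_model, ffn_dim, rng, dtype)
        self.ffn2 = Linear(ffn_dim, d_model, rng, dtype)
        self.norm2 = LayerNorm(d_model, dtype=dtype)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        x = self.norm1(x + self.attn(x, mask))
        x = self.norm2(x + self.ffn2(self.ffn1(x).relu()))
        # zero out padded instance tokens so downstream stages see exact zeros
        return x * mask[:, :, None].astype(x.data.dtype)
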