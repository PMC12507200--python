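"""The multi-instance network: per-instance CNN features, a transformer
encoder across the instances of a bag, instance scoring, and bag-level
aggregation.

Architecture, per bag of up to `bag_size` CDR3 instances (slot order =
descending clone frequency):

1. each instance's positional-encoded 24x15 matrix is treated as 15 input
   channels over 24 positions and passed through two conv->batchnorm->ReLU
   blocks (15->30 then 30->30 channels, kernel 8, stride 1, no padding),
   then globally max-pooled over positions to a 30-vector;
2. one transformer encoder layer (d_model 30, 10 heads, head dim 3,
   post-norm, position-wise FFN 30->60->30) mixes information across the
   bag's instance tokens; padded slots are masked out of attention;
3. a shared linear head (after dropout 0.4 in training) scores each
   instance: y~_j = W x_j + b;
4. the bag logit is an affine map over the slot-ordered score vector,
   z = W_f^T [y~_1 .. y~_k] + b_f with masked slots contributing zero, and
   the bag probability is sigmoid(z).

All weights use Xavier-normal initialization N(0, 2/(fan_in+fan_out));
biases start at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor
from .encoding import (EMBED_DIM, MAX_SEQ_LEN, EmbeddingMatrix, encode_bag,
                       positional_encoding_table)
from .io import InputError, RepertoireBag
from .nn import (BatchNorm1d, Conv1d, Linear, Module, TransformerEncoderLayer,
                 dropout, xavier_normal)

__all__ = ["ModelConfig", "BagPrediction", "MILClassifier", "init_model"]


@dataclass(frozen=True)
class ModelConfig:
    seq_len: int = MAX_SEQ_LEN
    embed_dim: int = EMBED_DIM
    conv_channels: int = 30
    conv_layers: int = 2
    kernel_size: int = 8
    d_model: int = 30
    n_heads: int = 10
    encoder_layers: int = 1
    ffn_dim: int | None = None  # defaults to 2 * d_model
    pe_dropout: float = 0.3
    head_dropout: float = 0.4
    bag_size: int = 100
    dtype: str = "float32"

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model={self.d_model} must be divisible by n_heads={self.n_heads}"
            )
        if self.kernel_size > self.seq_len:
            raise ValueError("kernel_size must not exceed seq_len")
        if self.ffn_dim is None:
            object.__setattr__(self, "ffn_dim", 2 * self.d_model)

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


@dataclass(frozen=True)
class BagPrediction:
    """Instance scores, the bag logit, and probability = sigmoid(logit)."""

    instance_scores: np.ndarray
    bag_logit: float
    probability: float


class MILClassifier(Module):
    """Learnable state + forward passes of the MIL network."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        dt = cfg.np_dtype
        self.cfg = cfg
        c = cfg.conv_channels
        self.conv1 = Conv1d(cfg.embed_dim, c, cfg.kernel_size, rng, dt)
        self.bn1 = BatchNorm1d(c, dtype=dt)
        self.conv2 = Conv1d(c, c, cfg.kernel_size, rng, dt)
        self.bn2 = BatchNorm1d(c, dtype=dt)
        self.encoder = TransformerEncoderLayer(cfg.d_model, cfg.n_heads,
                                               cfg.ffn_dim, rng, dt)
        self.score_head = Linear(cfg.d_model, 1, rng, dt)
        self.agg_weight = Tensor(
            xavier_normal(rng, (cfg.bag_size,), cfg.bag_size, 1, dt),
            requires_grad=True,
        )
        self.agg_bias = Tensor(np.zeros((), dtype=dt), requires_grad=True)

    # state_dict would otherwise trip on the config dataclass
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = super().state_dict(prefix)
        return {k: v for k, v in out.items() if not k.endswith("cfg")}

    # ------------------------------------------------------------------
    # batched training/inference forward
    # ------------------------------------------------------------------

    def forward_encoded(self, matrices: np.ndarray, mask: np.ndarray,
                        training: bool = False,
                        rng: np.random.Generator | None = None) -> Tensor:
        """Bag logits for a batch.

        matrices: (B, K, 24, 15) positional-encoded instance blocks with
        K <= bag_size; mask: (B, K) validity. Returns a (B,) logit tensor
        attached to the autograd tape.
        """
        if not np.isfinite(matrices).all():
            raise InputError("non-finite values in encoded input")
        b, k = mask.shape
        if k > self.cfg.bag_size:
            raise InputError(f"bag length {k} exceeds bag_size={self.cfg.bag_size}")
        if not mask.any(axis=1).all():
            raise InputError("every bag needs at least one unmasked instance")
        if training and rng is None:
            raise ValueError("training forward needs an rng for dropout")
        dt = self.cfg.np_dtype
        idx = np.flatnonzero(mask.reshape(-1))
        flat = matrices.reshape(b * k, self.cfg.seq_len, self.cfg.embed_dim)[idx]
        flat = flat.astype(dt, copy=True)
        if training and self.cfg.pe_dropout > 0.0:
            keep = 1.0 - self.cfg.pe_dropout
            flat *= (rng.random(flat.shape) < keep).astype(dt) / keep
        # (N_real, channels=embed_dim, positions=seq_len)
        x = Tensor(np.ascontiguousarray(flat.transpose(0, 2, 1)))
        feats = self._conv_stack(x, training)                      # (N_real, C)
        tokens = feats.scatter_rows(idx, b * k).reshape(b, k, self.cfg.d_model)
        enc = self.encoder(tokens, mask)                           # (B, K, d)
        h = dropout(enc, self.cfg.head_dropout, training,
                    rng if training else np.random.default_rng(0))
        scores = self.score_head(h).reshape(b, k)
        scores = scores * mask.astype(dt)
        w = self.agg_weight.take_rows(np.arange(k))
        return scores @ w + self.agg_bias

    def _conv_stack(self, x: Tensor, training: bool) -> Tensor:
        h = self.bn1(self.conv1(x), training).relu()
        h = self.bn2(self.conv2(h), training).relu()
        return h.max(axis=2)  # adaptive max pool to spatial size 1

    # ------------------------------------------------------------------
    # stage-wise numpy interfaces (inference-style building blocks)
    # ------------------------------------------------------------------

    def conv_features(self, encoded: np.ndarray, training: bool = False) -> np.ndarray:
        """(n, 24, 15) instance matrices -> (n, 30) pooled CNN features."""
        encoded = np.asarray(encoded)
        if not np.isfinite(encoded).all():
            raise InputError("non-finite values in encoded input")
        x = Tensor(np.ascontiguousarray(
            encoded.astype(self.cfg.np_dtype).transpose(0, 2, 1)))
        return self._conv_stack(x, training).data

    def encoder_forward(self, features: np.ndarray, mask: np.ndarray,
                        training: bool = False) -> np.ndarray:
        """(k, 30) instance features -> (k, 30) context-mixed features."""
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise InputError("all instances masked")
        x = Tensor(np.asarray(features, dtype=self.cfg.np_dtype)[None])
        return self.encoder(x, mask[None]).data[0]

    def instance_scores(self, encoded: np.ndarray, training: bool = False,
                        rng: np.random.Generator | None = None) -> np.ndarray:
        """Shared linear scoring head over (k, 30) features -> (k,) scores."""
        x = Tensor(np.asarray(encoded, dtype=self.cfg.np_dtype))
        x = dropout(x, self.cfg.head_dropout, training,
                    rng if rng is not None else np.random.default_rng(0))
        return self.score_head(x).data[:, 0]

    def aggregate_bag(self, scores: np.ndarray, mask: np.ndarray) -> BagPrediction:
        """Affine slot-weighted aggregation of instance scores -> probability."""
        scores = np.asarray(scores, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        k = scores.shape[0]
        if k > self.cfg.bag_size:
            raise InputError(f"{k} scores exceed bag_size={self.cfg.bag_size}")
        padded = np.zeros(self.cfg.bag_size)
        padded[:k] = np.where(mask, scores, 0.0)
        logit = float(self.agg_weight.data.astype(float) @ padded
                      + float(self.agg_bias.data))
        prob = float(1.0 / (1.0 + np.exp(-logit))) if logit > -50 else np.exp(logit)
        return BagPrediction(instance_scores=scores, bag_logit=logit,
                             probability=prob)


def init_model(cfg: ModelConfig = ModelConfig(), seed: int = 0) -> MILClassifier:
    """Build a classifier with Xavier-initialized weights; deterministic in seed."""
    return MILClassifier(cfg, np.random.default_rng(seed))


def predict_bag(bag: RepertoireBag, model: MILClassifier, M: EmbeddingMatrix,
                threshold: float = 0.5) -> tuple[int, BagPrediction]:
    """End-to-end inference on one preprocessed bag.

    Returns (label, prediction) where label = 1 iff probability strictly
    exceeds the threshold.
    """
    enc = encode_bag(bag, M, bag_size=model.cfg.bag_size)
    pe = positional_encoding_table(d_model=model.cfg.embed_dim)
    mats = enc.matrices + pe.values[: model.cfg.seq_len]
    mats[~enc.mask] = 0.0
    feats = model.conv_features(mats[enc.mask])
    k = int(enc.mask.sum())
    ctx = model.encoder_forward(feats, np.ones(k, dtype=bool))
    scores = model.instance_scores(ctx)
    pred = model.aggregate_bag(scores, np.ones(k, dtype=bool))
    return int(pred.probability > threshold), pred
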