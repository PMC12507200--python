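"""Loss, optimization, early stopping and iterated K-fold cross-validation.

Training minimizes the mean binary cross-entropy on bag logits,

    loss(z, y) = max(z, 0) - z*y + ln(1 + exp(-|z|)),

with Adam (alpha = 5e-4, beta1 = 0.9, beta2 = 0.999, eps = 1e-8), mini-batches
of 64 bags, and early stopping on a monitored validation quantity
(validation loss by default) with a patience of 300 epochs; the parameters
from the best-validation epoch are returned, not the last-epoch parameters.

The evaluation protocol is n-times-repeated K-fold cross-validation (the
study conditions use n = 100, K = 5): each repeat shuffles the bags, splits
them into K folds, holds each fold out as a test set in turn, splits the
remainder 8:2 into train/validation, trains, and evaluates on the held-out
fold.  Metrics are averaged over all n*K fold evaluations.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from ._autograd import Tensor
from .encoding import (EmbeddingMatrix, encode_bag, load_embedding_matrix,
                       positional_encoding_table)
from .evaluation import MetricsReport, evaluate_predictions, roc_auc
from .io import InputError, RepertoireBag
from .model import MILClassifier, ModelConfig, init_model

__all__ = [
    "TrainConfig",
    "CVConfig",
    "Adam",
    "bce_with_logits",
    "split_train_val",
    "train_model",
    "iterated_kfold",
    "derive_seed",
    "encode_dataset",
    "predict_dataset",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 2000
    batch_size: int = 64
    learning_rate: float = 0.0005
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    patience: int = 300
    val_fraction: float = 0.2
    monitor: str = "val_loss"  # or "val_auc"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must be in (0, 1)")
        if self.patience >= self.epochs:
            raise ValueError("patience must be smaller than epochs")


@dataclass(frozen=True)
class CVConfig:
    n_repeats: int = 100
    K: int = 5
    shuffle_seed: int = 0

    def __post_init__(self):
        if self.K < 2 or self.n_repeats < 1:
            raise ValueError("need K >= 2 and n_repeats >= 1")


def derive_seed(*parts) -> int:
    """Deterministically mix seed components into a 31-bit integer."""
    return zlib.crc32(":".join(str(p) for p in parts).encode()) & 0x7FFFFFFF


def bce_with_logits(z, y) -> float:
    """Mean binary cross-entropy on logits; stable for large |z|."""
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))))


class Adam(object):
    """Adam with bias-corrected first/second moments:

        m_t = b1 m_{t-1} + (1-b1) g_t
        v_t = b2 v_{t-1} + (1-b2) g_t^2
        theta_t = theta_{t-1} - alpha * (m_t/(1-b1^t)) / (sqrt(v_t/(1-b2^t)) + eps)
    """

    def __init__(self, params: Sequence[Tensor], lr: float = 0.0005,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data = (p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
                      ).astype(p.data.dtype)


def split_train_val(bags: Sequence[RepertoireBag], val_fraction: float,
                    seed: int) -> tuple[list[RepertoireBag], list[RepertoireBag]]:
    """Stratified-by-label random split; deterministic given the seed."""
    labels = [b.label for b in bags]
    if any(l is None for l in labels):
        raise InputError("all bags must be labeled for splitting")
    for cls in (0, 1):
        if labels.count(cls) < 2:
            raise InputError(f"class {cls} has fewer than 2 bags")
    idx = np.arange(len(bags))
    train_idx, val_idx = train_test_split(
        idx, test_size=val_fraction, stratify=np.asarray(labels),
        random_state=seed, shuffle=True)
    return [bags[i] for i in sorted(train_idx)], [bags[i] for i in sorted(val_idx)]


def encode_dataset(bags: Sequence[RepertoireBag], M: EmbeddingMatrix,
                   bag_size: int = 100, trim: bool = True
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack bags into arrays (X: (n, K, 24, 15), mask: (n, K), y: (n,)).

    Positional encodings are added here (they are fixed); with `trim` the
    slot axis is cut to the largest occupied slot count to save compute,
    which leaves predictions unchanged by padding invariance.
    """
    pe = positional_encoding_table().values[:24]
    encs = [encode_bag(b, M, bag_size=bag_size, dtype=np.float32) for b in bags]
    X = np.stack([e.matrices for e in encs])
    mask = np.stack([e.mask for e in encs])
    X += pe[None, None].astype(X.dtype)
    X[~mask] = 0.0
    y = np.array([-1 if b.label is None else b.label for b in bags], dtype=np.int64)
    if trim:
        k_max = int(mask.sum(axis=1).max())
        X, mask = X[:, :k_max], mask[:, :k_max]
    return X, mask, y


def _forward_logits(model: MILClassifier, X: np.ndarray, mask: np.ndarray,
                    chunk: int = 128) -> np.ndarray:
    out = []
    for i in range(0, len(X), chunk):
        out.append(model.forward_encoded(X[i:i + chunk], mask[i:i + chunk],
                                         training=False).data)
    return np.concatenate(out)


def train_model(train: Sequence[RepertoireBag], val: Sequence[RepertoireBag],
                model_cfg: ModelConfig = ModelConfig(),
                train_cfg: TrainConfig = TrainConfig(),
                embedding: EmbeddingMatrix | None = None,
                monitor_fn: Callable[[MILClassifier, int, np.ndarray, np.ndarray,
                                      float], float] | None = None
                ) -> tuple[MILClassifier, list[dict]]:
    """Train on `train`, early-stop on `val`; returns (best model, history).

    `monitor_fn(model, epoch, val_probs, val_labels, val_loss)` may override
    the monitored quantity; the monitored value is minimized ("val_auc" is
    negated internally).  Single-threaded execution with fixed seeds is
    bitwise reproducible.
    """
    if len(train) == 0 or len(val) == 0:
        raise InputError("train and validation sets must be nonempty")
    M = embedding if embedding is not None else load_embedding_matrix()
    Xtr, mtr, ytr = encode_dataset(train, M, model_cfg.bag_size)
    Xva, mva, yva = encode_dataset(val, M, model_cfg.bag_size)
    model = init_model(model_cfg, seed=derive_seed(train_cfg.seed, "init"))
    opt = Adam(model.parameters(), lr=train_cfg.learning_rate,
               beta1=train_cfg.beta1, beta2=train_cfg.beta2, eps=train_cfg.eps)
    rng = np.random.default_rng(derive_seed(train_cfg.seed, "batches"))
    best_value = np.inf
    best_epoch = 0
    best_state = model.state_dict()
    history: list[dict] = []
    n = len(train)
    for epoch in range(1, train_cfg.epochs + 1):
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, train_cfg.batch_size):
            sel = perm[start:start + train_cfg.batch_size]
            model.zero_grad()
            logits = model.forward_encoded(Xtr[sel], mtr[sel], training=True,
                                           rng=rng)
            loss = logits.bce_with_logits(ytr[sel].astype(np.float64)).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss.data!r}")
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val_logits = _forward_logits(model, Xva, mva)
        val_loss = bce_with_logits(val_logits, yva)
        val_probs = 1.0 / (1.0 + np.exp(-val_logits.astype(np.float64)))
        val_auc = roc_auc(yva, val_probs) if len(np.unique(yva)) > 1 else None
        if monitor_fn is not None:
            value = float(monitor_fn(model, epoch, val_probs, yva, val_loss))
        elif train_cfg.monitor == "val_auc":
            if val_auc is None:
                raise InputError("val_auc monitoring needs both classes in val")
            value = -val_auc
        else:
            value = val_loss
        history.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                        "val_loss": val_loss, "val_auc": val_auc,
                        "monitored": value})
        if value < best_value:
            best_value = value
            best_epoch = epoch
            best_state = model.state_dict()
        if epoch - best_epoch >= train_cfg.patience:
            break
    model.load_state_dict(best_state)
    return model, history


def predict_dataset(model: MILClassifier, bags: Sequence[RepertoireBag],
                    embedding: EmbeddingMatrix | None = None) -> np.ndarray:
    """Inference probabilities for a list of preprocessed bags."""
    M = embedding if embedding is not None else load_embedding_matrix()
    X, mask, _ = encode_dataset(bags, M, model.cfg.bag_size)
    logits = _forward_logits(model, X, mask)
    return 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))


def iterated_kfold(dataset: Sequence[RepertoireBag],
                   cv_cfg: CVConfig = CVConfig(),
                   model_cfg: ModelConfig = ModelConfig(),
                   train_cfg: TrainConfig = TrainConfig(),
                   embedding: EmbeddingMatrix | None = None) -> dict:
    """n-times-repeated K-fold cross-validation.

    Returns {"folds": [...], "aggregate": {...}} where each fold record
    carries (iteration, fold, sample ids, MetricsReport).  Train+val and
    test ids are disjoint by construction and re-checked here.
    """
    from .evaluation import aggregate_cv_metrics

    labels = np.array([b.label for b in dataset])
    if len(np.unique(labels)) < 2:
        raise InputError("dataset must contain both classes")
    if len(dataset) < cv_cfg.K:
        raise InputError("need at least K bags")
    M = embedding if embedding is not None else load_embedding_matrix()
    fold_records: list[dict] = []
    for it in range(cv_cfg.n_repeats):
        rng = np.random.default_rng(derive_seed(cv_cfg.shuffle_seed, "shuffle", it))
        perm = rng.permutation(len(dataset))
        folds = np.array_split(perm, cv_cfg.K)  # first |n| mod K folds get +1
        for fold_i, test_idx in enumerate(folds):
            rest_idx = np.concatenate([f for j, f in enumerate(folds) if j != fold_i])
            rest = [dataset[i] for i in rest_idx]
            fold_seed = derive_seed(cv_cfg.shuffle_seed, it, fold_i)
            tr, va = split_train_val(rest, train_cfg.val_fraction, fold_seed)
            fold_train_cfg = TrainConfig(**{**train_cfg.__dict__, "seed": fold_seed})
            test = [dataset[i] for i in test_idx]
            test_ids = {b.sample_id for b in test}
            assert not test_ids & {b.sample_id for b in tr + va}, "CV leakage"
            model, _ = train_model(tr, va, model_cfg, fold_train_cfg, embedding=M)
            probs = predict_dataset(model, test, embedding=M)
            y = np.array([b.label for b in test])
            report = evaluate_predictions(y, probs, threshold=0.5)
            fold_records.append({"iteration": it, "fold": fold_i,
                                 "test_ids": sorted(test_ids), "report": report})
    reports = [r["report"] for r in fold_records]
    iter_ids = [r["iteration"] for r in fold_records]
    return {"folds": fold_records,
            "aggregate": aggregate_cv_metrics(reports, iter_ids)}
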