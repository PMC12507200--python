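"""End-to-end experiment helpers built from the library modules.

The main entry point, :func:`signal_recovery`, runs the whole pipeline on a
synthetic dataset with planted motifs: generate -> preprocess -> hold out a
stratified test split -> train with early stopping -> score the test bags.
It is used by the acceptance checks and by the command line.
"""

from __future__ import annotations

import numpy as np

from .encoding import load_embedding_matrix
from .evaluation import evaluate_predictions, roc_auc, threshold_scan
from .model import ModelConfig
from .preprocess import PreprocessConfig, preprocess_dataset
from .synthetic import SimConfig, generate_dataset
from .training import (TrainConfig, derive_seed, predict_dataset,
                       split_train_val, train_model)

__all__ = ["signal_recovery"]


def signal_recovery(seed: int, planted_fraction: float = 0.3,
                    n_positive: int = 60, n_negative: int = 60,
                    motifs: tuple[str, ...] = ("WQDR",),
                    epochs: int = 300, patience: int = 60,
                    test_fraction: float = 0.2, scan: bool = False) -> dict:
    """Train on simulated repertoires and report held-out performance.

    Returns a dict with the held-out AUC, the threshold-0.5 metrics report,
    and bookkeeping (epochs run, split sizes).  With planted_fraction = 0
    the two classes are identically distributed and the expected held-out
    AUC is ~0.5.
    """
    sim = SimConfig(n_positive=n_positive, n_negative=n_negative,
                    motifs=motifs, planted_fraction=planted_fraction,
                    seed=derive_seed(seed, "simulate"))
    bags = generate_dataset(sim)
    clean, rejected = preprocess_dataset(bags, PreprocessConfig())
    assert not rejected, "synthetic bags are valid by construction"
    dev, test = split_train_val(clean, test_fraction, derive_seed(seed, "test-split"))
    train, val = split_train_val(dev, 0.2, derive_seed(seed, "val-split"))
    model_cfg = ModelConfig()
    train_cfg = TrainConfig(epochs=epochs, patience=patience,
                            seed=derive_seed(seed, "train"))
    M = load_embedding_matrix()
    model, history = train_model(train, val, model_cfg, train_cfg, embedding=M)
    probs = predict_dataset(model, test, embedding=M)
    y = np.array([b.label for b in test])
    report = evaluate_predictions(y, probs, threshold=0.5, scan=scan)
    return {
        "test_auc": roc_auc(y, probs),
        "report": report,
        "optimal_threshold_intervals": threshold_scan(y, probs)[1] if scan else None,
        "epochs_run": len(history),
        "n_train": len(train), "n_val": len(val), "n_test": len(test),
        "model": model,
        "history": history,
    }
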