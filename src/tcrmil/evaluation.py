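"""Confusion-based metrics, ROC/AUC, the combined score and threshold scans.

Conventions:

- a sample is predicted positive only when its probability strictly exceeds
  the threshold;
- ACC = (TP+TN)/N, SEN = TP/(TP+FN), SPE = TN/(TN+FP);
- metrics with a zero denominator (a fold without positives or without
  negatives) are reported as ``None`` — an explicit undefined flag — rather
  than silently coerced to 0, so cross-validation means are not corrupted;
- the combined score is the arithmetic mean of ACC, SEN and SPE, used to
  pick an operating threshold;
- AUC is the probability that a random positive outranks a random negative
  (ties counted 1/2), equal to trapezoidal ROC integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .io import InputError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "basic_metrics",
    "roc_auc",
    "combined_score",
    "threshold_scan",
    "evaluate_predictions",
    "aggregate_cv_metrics",
    "default_threshold_grid",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """Metrics of one evaluation (e.g. one CV fold) at a fixed threshold."""

    threshold: float
    counts: ConfusionCounts
    acc: float | None
    sen: float | None
    spe: float | None
    auc: float | None
    combined: float | None
    curve: list[dict] = field(default_factory=list)  # optional per-threshold scan

    def to_dict(self) -> dict:
        return asdict(self)


def _check_pairs(labels: Sequence[int], probabilities: Sequence[float]):
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise InputError(f"labels {y.shape} and probabilities {p.shape} must be "
                         "equal-length 1-D sequences")
    if y.size == 0:
        raise InputError("empty evaluation input")
    if not np.isin(y, (0, 1)).all():
        raise InputError("labels must be 0/1")
    return y.astype(int), p


def confusion_counts(labels: Sequence[int], probabilities: Sequence[float],
                     threshold: float = 0.5) -> ConfusionCounts:
    y, p = _check_pairs(labels, probabilities)
    pred = p > threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & (y == 1))),
        TN=int(np.sum(~pred & (y == 0))),
        FP=int(np.sum(pred & (y == 0))),
        FN=int(np.sum(~pred & (y == 1))),
    )


def basic_metrics(c: ConfusionCounts) -> tuple[float, float | None, float | None]:
    """(ACC, SEN, SPE); SEN/SPE are None when their denominator is zero."""
    if c.total == 0:
        raise InputError("empty confusion counts")
    acc = (c.TP + c.TN) / c.total
    sen = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None
    spe = c.TN / (c.TN + c.FP) if (c.TN + c.FP) > 0 else None
    return acc, sen, spe


def roc_auc(labels: Sequence[int], probabilities: Sequence[float]) -> float | None:
    """AUC, or None (undefined) when only one class is present."""
    y, p = _check_pairs(labels, probabilities)
    if len(np.unique(y)) < 2:
        return None
    return float(roc_auc_score(y, p))


def combined_score(acc: float | None, sen: float | None,
                   spe: float | None) -> float | None:
    """Arithmetic mean of ACC, SEN, SPE; None if any component is undefined."""
    if acc is None or sen is None or spe is None:
        return None
    return (acc + sen + spe) / 3.0


def default_threshold_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)


def threshold_scan(labels: Sequence[int], probabilities: Sequence[float],
                   grid: Sequence[float] | None = None
                   ) -> tuple[list[dict], list[tuple[float, float]]]:
    """Evaluate the combined score on a threshold grid.

    Returns (curve, intervals): `curve` has one record per grid threshold
    (thresholds where SEN or SPE is undefined are flagged and excluded from
    the maximization); `intervals` lists the contiguous [theta_min,
    theta_max] grid runs attaining the maximal combined score.
    """
    if grid is None:
        grid = default_threshold_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise InputError("threshold grid must be nonempty and strictly increasing")
    curve: list[dict] = []
    for theta in grid:
        c = confusion_counts(labels, probabilities, float(theta))
        acc, sen, spe = basic_metrics(c)
        comb = combined_score(acc, sen, spe)
        curve.append({"threshold": float(theta), "acc": acc, "sen": sen,
                      "spe": spe, "combined": comb,
                      "undefined": comb is None})
    defined = [(i, r["combined"]) for i, r in enumerate(curve) if not r["undefined"]]
    if not defined:
        return curve, []
    best = max(v for _, v in defined)
    best_idx = sorted(i for i, v in defined if v >= best - 1e-12)
    intervals: list[tuple[float, float]] = []
    start = prev = best_idx[0]
    for i in best_idx[1:]:
        if i == prev + 1:
            prev = i
            continue
        intervals.append((float(grid[start]), float(grid[prev])))
        start = prev = i
    intervals.append((float(grid[start]), float(grid[prev])))
    return curve, intervals


def evaluate_predictions(labels: Sequence[int], probabilities: Sequence[float],
                         threshold: float = 0.5, scan: bool = False,
                         warn_single_class: bool = True) -> MetricsReport:
    """Full metrics report at one threshold (optionally with a grid scan)."""
    c = confusion_counts(labels, probabilities, threshold)
    acc, sen, spe = basic_metrics(c)
    auc = roc_auc(labels, probabilities)
    if auc is None and warn_single_class:
        warnings.warn("single-class evaluation set: AUC undefined", stacklevel=2)
    curve: list[dict] = []
    if scan:
        curve, _ = threshold_scan(labels, probabilities)
    return MetricsReport(threshold=threshold, counts=c, acc=acc, sen=sen, spe=spe,
                         auc=auc, combined=combined_score(acc, sen, spe),
                         curve=curve)


def roc_points(labels: Sequence[int], probabilities: Sequence[float]) -> np.ndarray:
    """(FPR, TPR, threshold) points of the ROC curve, for external plotting."""
    y, p = _check_pairs(labels, probabilities)
    fpr, tpr, thr = roc_curve(y, p)
    return np.column_stack([fpr, tpr, thr])


def _mean_ignore_none(values: list[float | None]) -> tuple[float | None, int]:
    defined = [v for v in values if v is not None]
    if not defined:
        return None, 0
    return float(np.mean(defined)), len(defined)


def aggregate_cv_metrics(reports: Sequence[MetricsReport],
                         iteration_ids: Sequence[int] | None = None) -> dict:
    """Aggregate per-fold reports: arithmetic mean of each metric over all
    folds, plus a 95% empirical-percentile interval over iteration means.

    `iteration_ids` assigns each report to a repeat of the K-fold protocol;
    when omitted every report is its own iteration.  Undefined (None)
    metrics are excluded from means; the count of defined folds is reported.
    """
    if len(reports) == 0:
        raise InputError("no reports to aggregate")
    if iteration_ids is None:
        iteration_ids = list(range(len(reports)))
    out: dict = {"n_folds": len(reports)}
    for name in ("acc", "sen", "spe", "auc", "combined"):
        values = [getattr(r, name) for r in reports]
        mean, n_defined = _mean_ignore_none(values)
        per_iter: dict[int, list[float]] = {}
        for it, v in zip(iteration_ids, values):
            if v is not None:
                per_iter.setdefault(it, []).append(v)
        iter_means = np.array([np.mean(v) for _, v in sorted(per_iter.items())])
        if iter_means.size:
            lo, hi = np.percentile(iter_means, [2.5, 97.5])
            ci = (float(lo), float(hi))
        else:
            ci = None
        out[name] = {"mean": mean, "n_defined": n_defined, "ci95": ci}
    return out
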