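"""Per-target decision-threshold calibration.

Raw posteriors from the per-target models are turned into binary calls
either with the default Bayes rule (active iff P(active) > 0.5) or with
a target-specific threshold.  Thresholds are calibrated by stratified
k-fold cross-validation: out-of-fold activity probabilities are swept
over a fixed grid (0.1 to 1.0, step 0.001) and, for each of four
metrics (F1, accuracy, precision, recall), the grid point maximizing
the fold-averaged metric becomes that metric's threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model as nbmodel
from .training import DegenerateClassWarning

GRID_START = 0.1
GRID_STOP = 1.0
GRID_STEP = 0.001
METRICS = ("f1", "accuracy", "precision", "recall")


def default_grid() -> np.ndarray:
    """The 901-point threshold grid 0.100, 0.101, ..., 1.000."""
    n = int(round((GRID_STOP - GRID_START) / GRID_STEP)) + 1
    return np.round(GRID_START + GRID_STEP * np.arange(n), 3)


@dataclass(frozen=True)
class ThresholdSet:
    """Per-target optimal thresholds, one per calibration metric."""

    target_id: str
    thresholds: dict[str, float]
    metric_at_optimum: dict[str, float] = field(default_factory=dict)
    grid_step: float = GRID_STEP


def stratified_folds(labels: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Assign each example to one of ``k`` folds, preserving class balance.

    Deterministic for a fixed seed.  Warns when a class has fewer than
    ``k`` members, since some folds will then lack that class.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.size < 2:
        raise ValueError("both classes must be present for stratified folds")
    if counts.min() < k:
        warnings.warn(
            f"smallest class has {counts.min()} members for {k} folds; "
            "some folds will lack it",
            DegenerateClassWarning,
        )
    # seeded shuffle within each class, then round-robin dealing: every
    # fold's class count is within one example of the exact proportion
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=np.int64)
    for value in np.unique(labels):
        idx = np.flatnonzero(labels == value)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def sweep_thresholds(
    scores: np.ndarray, truths: np.ndarray, grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Confusion metrics at every grid threshold.

    A compound is called active iff its score is >= the threshold
    (grid thresholds are inclusive).  Precision is 0 when nothing is
    predicted active, and F1 is 0 when precision + recall is 0.
    Returns a DataFrame with columns threshold, precision, recall,
    accuracy, f1.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truths = np.asarray(truths).astype(bool)
    if scores.size == 0:
        raise ValueError("cannot sweep thresholds over empty scores")
    if scores.shape != truths.shape:
        raise ValueError("scores and truths differ in length")
    if grid is None:
        grid = default_grid()
    pred = scores[:, None] >= grid[None, :]          # (n, n_grid)
    tp = (pred & truths[:, None]).sum(axis=0).astype(np.float64)
    fp = (pred & ~truths[:, None]).sum(axis=0).astype(np.float64)
    fn = truths.sum() - tp
    tn = (~truths).sum() - fp
    n = float(scores.size)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        accuracy = (tp + tn) / n
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    return pd.DataFrame(
        {"threshold": grid, "precision": precision, "recall": recall,
         "accuracy": accuracy, "f1": f1}
    )


def optimal_threshold(per_fold_tables: list[pd.DataFrame], metric: str) -> float:
    """Grid value maximizing the fold-averaged metric.

    Ties break toward the smallest threshold; averaged values within
    1e-12 of the maximum count as tied, so mathematically equal metrics
    reached through different confusion counts (e.g. F1 = 2/3 as
    0.5*1.0 or (5/9)*(5/6)) do not resolve on a final-ulp rounding
    difference.  If the metric is zero everywhere, the smallest grid
    value is returned with a warning.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if not per_fold_tables:
        raise ValueError("need at least one fold table")
    grid = per_fold_tables[0]["threshold"].to_numpy()
    avg = np.mean([t[metric].to_numpy() for t in per_fold_tables], axis=0)
    if avg.max() <= 0.0:
        warnings.warn(
            f"{metric} is zero over the whole grid; threshold degenerate",
            DegenerateClassWarning,
        )
        return float(grid[0])
    return float(grid[int(np.flatnonzero(avg >= avg.max() - 1e-12)[0])])


def cross_val_scores(
    fps: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
    alpha: float = 1.0,
    priors: str = "empirical",
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold activity probabilities via per-fold refits.

    For each fold, a model is fitted on the remaining k-1 folds and
    scores the held-out fold.  Returns (scores, fold assignment).
    """
    fps = np.asarray(fps)
    labels = np.asarray(labels).astype(np.int8)
    folds = stratified_folds(labels, k=k, seed=seed)
    scores = np.empty(len(labels), dtype=np.float64)
    for f in np.unique(folds):
        train = folds != f
        m = nbmodel.fit(fps[train], labels[train], alpha=alpha, priors=priors)
        scores[folds == f] = nbmodel.predict_proba(m, fps[folds == f])
    return scores, folds


def calibrate_target(
    fps: np.ndarray,
    labels: np.ndarray,
    target_id: str = "",
    k: int = 5,
    seed: int = 0,
    alpha: float = 1.0,
    priors: str = "empirical",
    grid: np.ndarray | None = None,
) -> ThresholdSet:
    """Full calibration for one target: CV scores, sweep, per-metric optimum."""
    if grid is None:
        grid = default_grid()
    scores, folds = cross_val_scores(fps, labels, k=k, seed=seed, alpha=alpha,
                                     priors=priors)
    tables = [
        sweep_thresholds(scores[folds == f], np.asarray(labels)[folds == f], grid)
        for f in np.unique(folds)
        if np.asarray(labels)[folds == f].size
    ]
    thresholds, at_opt = {}, {}
    for metric in METRICS:
        t = optimal_threshold(tables, metric)
        thresholds[metric] = t
        avg = np.mean([tab[metric].to_numpy() for tab in tables], axis=0)
        at_opt[metric] = float(avg[int(np.searchsorted(grid, t))])
    return ThresholdSet(target_id=target_id, thresholds=thresholds,
                        metric_at_optimum=at_opt, grid_step=GRID_STEP)


def apply_threshold(score: float, threshold: float | None = None) -> str:
    """Binary call from an activity probability.

    With an explicit calibrated threshold t: active iff score >= t.
    With no threshold, the default Bayes rule applies: active iff the
    activity probability strictly exceeds the inactivity probability,
    i.e. score > 0.5.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score must be a probability, got {score}")
    if threshold is None:
        return "active" if score > 0.5 else "inactive"
    return "active" if score >= threshold else "inactive"
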