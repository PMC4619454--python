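"""Performance statistics for target-prediction models.

Covers confusion-matrix metrics, precision-recall AUC, BEDROC early
recognition, the log2 enrichment ratio comparing calibrated thresholds
to the default decision rule, top-k panel ranking metrics, and a paired
Wilcoxon signed-rank comparison between two model families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import precision_recall_curve


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EnrichmentScore:
    """log2 ratio of a metric with vs without a calibrated threshold.

    ``flag`` is ``"ok"``, ``"infinite"`` (denominator zero, numerator
    positive) or ``"undefined"`` (both zero; excluded from summaries).
    """

    score_threshold: float
    score_no_threshold: float
    r: float
    flag: str = "ok"


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Precision, recall, accuracy and F1 with zero-division -> 0."""
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    accuracy = (c.tp + c.tn) / c.n if c.n else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"precision": precision, "recall": recall, "accuracy": accuracy, "f1": f1}


def pr_auc(scores: np.ndarray, truths: np.ndarray) -> float:
    """Area under the precision-recall curve, trapezoidal over recall.

    The curve is evaluated at every score cut-point and anchored at
    recall 0 with the precision of the strictest cut-point, so constant
    scores integrate exactly to the positive prevalence.  Requires both
    classes; invariant to strictly monotone score transforms.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truths = np.asarray(truths).astype(int)
    if truths.min() == truths.max():
        raise ValueError("PR AUC needs both classes in the truth labels")
    precision, recall, _ = precision_recall_curve(truths, scores)
    # drop sklearn's (recall=0, precision=1) sentinel; order by ascending
    # recall and anchor horizontally at recall 0
    precision, recall = precision[:-1][::-1], recall[:-1][::-1]
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    return float(np.trapezoid(precision, recall))


def bedroc(scores: np.ndarray, truths: np.ndarray, alpha: float = 20.0) -> float:
    """BEDROC early-recognition score in [0, 1].

    Compounds are ranked by descending score (stable order on ties) and
    the exponentially rank-weighted sum S = sum over actives of
    exp(-alpha * rank / N) is normalized between its worst (all actives
    last) and best (all actives first) configurations:
    (S - S_min) / (S_max - S_min).  Equals 1 when every active precedes
    every inactive and 0 in the reverse, and is invariant to monotone
    score transforms.  alpha = 20 focuses on roughly the top 8% of the
    list.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truths = np.asarray(truths).astype(bool)
    n = truths.size
    n_act = int(truths.sum())
    if n_act < 1 or n_act >= n:
        raise ValueError("BEDROC needs at least one active and one inactive")
    order = np.argsort(-scores, kind="stable")
    ranks = np.flatnonzero(truths[order]) + 1  # 1-based ranks of actives
    s = np.exp(-alpha * ranks / n).sum()
    best = np.exp(-alpha * np.arange(1, n_act + 1) / n).sum()
    worst = np.exp(-alpha * np.arange(n - n_act + 1, n + 1) / n).sum()
    return float((s - worst) / (best - worst))


def r_score(score_with: float, score_without: float) -> EnrichmentScore:
    """Enrichment ratio R = log2(metric with threshold / without).

    Positive values favour the calibrated threshold; negative values
    favour the default P(active) > P(inactive) rule.
    """
    if score_with < 0 or score_without < 0:
        raise ValueError("metric scores must be non-negative")
    if score_without == 0.0:
        if score_with == 0.0:
            return EnrichmentScore(score_with, score_without, float("nan"), "undefined")
        return EnrichmentScore(score_with, score_without, float("inf"), "infinite")
    if score_with == 0.0:
        return EnrichmentScore(score_with, score_without, float("-inf"), "infinite")
    return EnrichmentScore(score_with, score_without,
                           float(np.log2(score_with / score_without)), "ok")


def topk_eval(
    rankings: dict[str, list[str]],
    truth: dict[str, set[str]],
    k: int,
) -> dict[str, float]:
    """Recall@k and precision@k of per-compound ranked target lists.

    recall@k is the fraction of a compound's true targets found in its
    top k; precision@k is true targets in the top k divided by k.  Both
    are averaged over compounds with at least one true target.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    recalls, precisions = [], []
    for compound, ranked in rankings.items():
        true_targets = truth.get(compound, set())
        if not true_targets:
            continue
        hits = len(set(ranked[:k]) & true_targets)
        recalls.append(hits / len(true_targets))
        precisions.append(hits / k)
    if not recalls:
        return {"recall_at_k": 0.0, "precision_at_k": 0.0}
    return {"recall_at_k": float(np.mean(recalls)),
            "precision_at_k": float(np.mean(precisions))}


def paired_comparison(metrics_a: np.ndarray, metrics_b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value on per-target paired metrics.

    Zero differences are discarded (the standard convention).  Returns
    p = 1 with a warning when every pair is tied.  Requires >= 6 pairs.
    """
    a = np.asarray(metrics_a, dtype=np.float64)
    b = np.asarray(metrics_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired metric vectors differ in length")
    if a.size < 6:
        raise ValueError("paired comparison needs at least 6 pairs")
    if np.all(a == b):
        warnings.warn("all paired differences are zero; p-value is 1", UserWarning)
        return 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.pvalue)


def cross_validated_class_metrics(
    cls,
    k: int = 5,
    seed: int = 0,
    alpha: float = 1.0,
    priors: str = "empirical",
    threshold: float | None = None,
) -> dict[str, float]:
    """Stratified k-fold CV metrics for one target class.

    Out-of-fold activity probabilities are binarized with the default
    P(active) > 0.5 rule (or an explicit inclusive threshold); the
    active-side precision/recall/F1 and the inactive-side recall are
    computed per fold and averaged, the per-fold-then-average convention
    used for internal validation of per-target models.
    """
    from .calibration import cross_val_scores  # local import avoids a cycle

    fps, labels = cls.training_matrix()
    scores, folds = cross_val_scores(fps, labels, k=k, seed=seed, alpha=alpha,
                                     priors=priors)
    labels = np.asarray(labels).astype(bool)
    per_fold = []
    for f in np.unique(folds):
        mask = folds == f
        calls = (scores[mask] > 0.5) if threshold is None else (scores[mask] >= threshold)
        truths = labels[mask]
        c = ConfusionCounts(
            tp=int((calls & truths).sum()), fp=int((calls & ~truths).sum()),
            tn=int((~calls & ~truths).sum()), fn=int((~calls & truths).sum()))
        m = confusion_metrics(c)
        m["inactive_recall"] = c.tn / (c.tn + c.fp) if c.tn + c.fp else 0.0
        per_fold.append(m)
    keys = per_fold[0].keys()
    return {key: float(np.mean([m[key] for m in per_fold])) for key in keys}


def summarize(values: np.ndarray) -> dict[str, float]:
    """Mean/median/std/min/max summary used in per-panel reports."""
    v = np.asarray([x for x in np.asarray(values, dtype=np.float64) if np.isfinite(x)])
    if v.size == 0:
        return {"mean": float("nan"), "median": float("nan"), "std": float("nan"),
                "min": float("nan"), "max": float("nan"), "n": 0}
    return {"mean": float(v.mean()), "median": float(np.median(v)),
            "std": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "min": float(v.min()), "max": float(v.max()), "n": int(v.size)}
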