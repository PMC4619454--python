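"""Bernoulli Naive Bayes models over binary fingerprints.

Each protein target gets a two-class (active vs inactive) model.  For a
query fingerprint x = (F_1, ..., F_n) the class-conditional likelihood
is the Bernoulli product

    P(x | C) = prod_i P(F_i|C)^{F_i} * (1 - P(F_i|C))^{1 - F_i}

so absent features explicitly count as evidence, and the posterior
follows from Bayes' theorem with the class priors.  Feature conditionals
are Laplace-smoothed empirical frequencies.  A separate multiclass model
over the whole target panel, trained on actives only, ranks targets by
their normalized posterior and serves as the activity-only baseline.

All computation is done in log space with the usual log-sum-exp
normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .training import TargetClass

FORMAT_VERSION = 1


class ModelFormatError(ValueError):
    """Raised when a persisted model is corrupt or configured differently."""


def _smoothed_log_probs(fps: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """log P(F_i=1|C) and log P(F_i=0|C) with add-alpha smoothing."""
    n = len(fps)
    counts = np.asarray(fps, dtype=np.float64).sum(axis=0)
    p = (counts + alpha) / (n + 2.0 * alpha)
    with np.errstate(divide="ignore"):
        return np.log(p), np.log1p(-p)


@dataclass
class TargetModel:
    """Fitted per-target Bernoulli NB parameters."""

    target_id: str
    log_p_active: np.ndarray      # log P(F_i=1 | active)
    log_q_active: np.ndarray      # log P(F_i=0 | active)
    log_p_inactive: np.ndarray
    log_q_inactive: np.ndarray
    log_prior_active: float
    log_prior_inactive: float
    alpha: float
    n_active: int
    n_inactive: int
    fp_config: dict = field(default_factory=lambda: {"n_bits": 2048, "radius": 2})

    @property
    def n_features(self) -> int:
        return self.log_p_active.shape[0]


def fit(
    fps: np.ndarray,
    labels: np.ndarray,
    alpha: float = 1.0,
    priors: str = "empirical",
    target_id: str = "",
    fp_config: dict | None = None,
) -> TargetModel:
    """Fit a two-class Bernoulli NB model.

    P(F_i|C) = (count of F_i=1 in C + alpha) / (N_C + 2 alpha); priors
    are the empirical class frequencies (or uniform if requested).
    Deterministic.  Raises on a single-class training set.
    """
    fps = np.asarray(fps)
    labels = np.asarray(labels).astype(np.int8)
    if fps.ndim != 2 or len(fps) != len(labels):
        raise ValueError("fingerprint matrix and labels do not align")
    n_act = int((labels == 1).sum())
    n_inact = int((labels == 0).sum())
    if n_act == 0 or n_inact == 0:
        raise ValueError(f"degenerate training set for {target_id!r}: one class absent")
    lp_a, lq_a = _smoothed_log_probs(fps[labels == 1], alpha)
    lp_i, lq_i = _smoothed_log_probs(fps[labels == 0], alpha)
    if priors == "empirical":
        pa = n_act / (n_act + n_inact)
    elif priors == "uniform":
        pa = 0.5
    else:
        raise ValueError(f"unknown priors mode {priors!r}")
    return TargetModel(
        target_id=target_id,
        log_p_active=lp_a, log_q_active=lq_a,
        log_p_inactive=lp_i, log_q_inactive=lq_i,
        log_prior_active=float(np.log(pa)),
        log_prior_inactive=float(np.log1p(-pa)),
        alpha=alpha, n_active=n_act, n_inactive=n_inact,
        fp_config=dict(fp_config) if fp_config else {"n_bits": fps.shape[1], "radius": 2},
    )


def fit_class(cls: TargetClass, alpha: float = 1.0, priors: str = "empirical",
              fp_config: dict | None = None) -> TargetModel:
    """Fit a :class:`TargetModel` directly from an assembled class."""
    fps, labels = cls.training_matrix()
    return fit(fps, labels, alpha=alpha, priors=priors, target_id=cls.target_id,
               fp_config=fp_config)


def log_likelihood(model: TargetModel, fp: np.ndarray, cls: str) -> float:
    """Log Bernoulli likelihood log P(fp | cls) under the fitted model.

    Present bits contribute log P(F_i|C); absent bits contribute
    log(1 - P(F_i|C)), so non-occurrence is explicitly penalized.
    """
    fp = np.asarray(fp, dtype=np.float64)
    if fp.shape[0] != model.n_features:
        raise ValueError(
            f"fingerprint length {fp.shape[0]} does not match model {model.n_features}"
        )
    if cls == "active":
        lp, lq = model.log_p_active, model.log_q_active
    elif cls == "inactive":
        lp, lq = model.log_p_inactive, model.log_q_inactive
    else:
        raise ValueError(f"unknown class {cls!r}")
    return float(fp @ lp + (1.0 - fp) @ lq)


def predict_proba(model: TargetModel, fps: np.ndarray) -> np.ndarray:
    """Posterior probability of activity for one or many fingerprints.

    Returns a scalar array for a single fingerprint or a vector for a
    (n, length) matrix; values are in (0, 1) for smoothed models.
    """
    fps = np.asarray(fps, dtype=np.float64)
    single = fps.ndim == 1
    if single:
        fps = fps[None, :]
    if fps.shape[1] != model.n_features:
        raise ValueError(
            f"fingerprint length {fps.shape[1]} does not match model {model.n_features}"
        )
    # sum_i F_i log p + (1-F_i) log q  ==  sum_i log q + F_i (log p - log q)
    ll_a = model.log_q_active.sum() + fps @ (model.log_p_active - model.log_q_active)
    ll_i = model.log_q_inactive.sum() + fps @ (model.log_p_inactive - model.log_q_inactive)
    ja = ll_a + model.log_prior_active
    ji = ll_i + model.log_prior_inactive
    m = np.maximum(ja, ji)
    pa = np.exp(ja - m) / (np.exp(ja - m) + np.exp(ji - m))
    return pa[0] if single else pa


@dataclass
class MulticlassModel:
    """Bernoulli NB over the target panel, trained on actives only."""

    target_ids: list[str]
    log_p: np.ndarray       # (n_targets, n_features) log P(F_i=1 | target)
    log_q: np.ndarray
    log_priors: np.ndarray  # (n_targets,)
    alpha: float
    n_per_target: np.ndarray
    fp_config: dict = field(default_factory=lambda: {"n_bits": 2048, "radius": 2})


def fit_multiclass(
    classes: list[TargetClass],
    alpha: float = 1.0,
    priors: str = "empirical",
    fp_config: dict | None = None,
) -> MulticlassModel:
    """Fit the activity-only multiclass model over >= 2 target classes.

    Each target is one class; only actives are used.  The posterior for
    a target expresses how probable the query's activity on that target
    is relative to the rest of the panel.
    """
    if len(classes) < 2:
        raise ValueError("multiclass model needs >= 2 target classes")
    lps, lqs, ns = [], [], []
    for cls in classes:
        lp, lq = _smoothed_log_probs(cls.active_fps, alpha)
        lps.append(lp)
        lqs.append(lq)
        ns.append(cls.n_active)
    ns_arr = np.asarray(ns, dtype=np.float64)
    if priors == "empirical":
        log_priors = np.log(ns_arr / ns_arr.sum())
    elif priors == "uniform":
        log_priors = np.full(len(classes), -np.log(len(classes)))
    else:
        raise ValueError(f"unknown priors mode {priors!r}")
    n_bits = classes[0].active_fps.shape[1]
    return MulticlassModel(
        target_ids=[c.target_id for c in classes],
        log_p=np.vstack(lps), log_q=np.vstack(lqs),
        log_priors=log_priors, alpha=alpha,
        n_per_target=ns_arr.astype(np.int64),
        fp_config=dict(fp_config) if fp_config else {"n_bits": n_bits, "radius": 2},
    )


def predict_targets_proba(model: MulticlassModel, fp: np.ndarray) -> np.ndarray:
    """Posterior over all panel targets for a query; sums to 1."""
    fp = np.asarray(fp, dtype=np.float64)
    if fp.shape[0] != model.log_p.shape[1]:
        raise ValueError("fingerprint length does not match multiclass model")
    joint = model.log_priors + model.log_q.sum(axis=1) + (model.log_p - model.log_q) @ fp
    joint -= joint.max()
    p = np.exp(joint)
    return p / p.sum()


def rank_targets(model: MulticlassModel, fp: np.ndarray, k: int) -> list[str]:
    """Top-k targets by descending posterior; ties keep panel order."""
    if not 1 <= k <= len(model.target_ids):
        raise ValueError(f"k must be in [1, {len(model.target_ids)}], got {k}")
    post = predict_targets_proba(model, fp)
    order = np.argsort(-post, kind="stable")
    return [model.target_ids[i] for i in order[:k]]


def save_model(model: TargetModel | MulticlassModel, path) -> None:
    """Persist a model losslessly with a version/config header."""
    if isinstance(model, TargetModel):
        meta = {
            "format_version": FORMAT_VERSION, "kind": "target",
            "target_id": model.target_id, "alpha": model.alpha,
            "n_active": model.n_active, "n_inactive": model.n_inactive,
            "log_prior_active": model.log_prior_active,
            "log_prior_inactive": model.log_prior_inactive,
            "fp_config": model.fp_config,
        }
        np.savez(
            path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            log_p_active=model.log_p_active, log_q_active=model.log_q_active,
            log_p_inactive=model.log_p_inactive, log_q_inactive=model.log_q_inactive,
        )
    elif isinstance(model, MulticlassModel):
        meta = {
            "format_version": FORMAT_VERSION, "kind": "multiclass",
            "target_ids": model.target_ids, "alpha": model.alpha,
            "fp_config": model.fp_config,
        }
        np.savez(
            path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            log_p=model.log_p, log_q=model.log_q,
            log_priors=model.log_priors, n_per_target=model.n_per_target,
        )
    else:
        raise TypeError(f"cannot save object of type {type(model).__name__}")


def load_model(path, expect_fp_config: dict | None = None) -> TargetModel | MulticlassModel:
    """Load a persisted model, refusing version or fingerprint mismatches."""
    try:
        data = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(data["meta"]).decode())
    except Exception as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if meta.get("format_version") != FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format version {meta.get('format_version')!r}"
        )
    if expect_fp_config is not None and meta.get("fp_config") != expect_fp_config:
        raise ModelFormatError(
            f"fingerprint configuration mismatch: model has {meta.get('fp_config')}, "
            f"expected {expect_fp_config}"
        )
    if meta["kind"] == "target":
        return TargetModel(
            target_id=meta["target_id"],
            log_p_active=data["log_p_active"], log_q_active=data["log_q_active"],
            log_p_inactive=data["log_p_inactive"], log_q_inactive=data["log_q_inactive"],
            log_prior_active=meta["log_prior_active"],
            log_prior_inactive=meta["log_prior_inactive"],
            alpha=meta["alpha"], n_active=meta["n_active"],
            n_inactive=meta["n_inactive"], fp_config=meta["fp_config"],
        )
    if meta["kind"] == "multiclass":
        return MulticlassModel(
            target_ids=meta["target_ids"], log_p=data["log_p"], log_q=data["log_q"],
            log_priors=data["log_priors"], alpha=meta["alpha"],
            n_per_target=data["n_per_target"], fp_config=meta["fp_config"],
        )
    raise ModelFormatError(f"unknown model kind {meta['kind']!r}")
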