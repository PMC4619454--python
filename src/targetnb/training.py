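"""Per-target training-set assembly and class balancing.

Bioactivity records are labelled active/inactive, grouped into
per-target classes, and the inactive side is brought to a fixed
active:inactive ratio either by undersampling an oversized experimental
inactive set or by topping up with *putative* inactives sampled from a
background compound pool via sphere exclusion: a candidate is accepted
only if its similarity to every active is below an exclusion radius,
chosen as the Tanimoto value covering a quantile (default 95%) of the
actives' nearest-neighbour similarity distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .chem import pairwise_tanimoto

ACTIVITY_TYPES_QUANTITATIVE = {"IC50", "EC50", "Ki", "Kd"}

#: Exclusion radius used when the nearest-neighbour distribution is not
#: recomputed: the Tc covering 95% of active nearest-neighbour pairs on
#: the large public bioactivity corpus the method was developed on.
DEFAULT_EXCLUSION_TC = 0.424
DEFAULT_COVERAGE = 0.95
DEFAULT_INACTIVE_RATIO = 100
DEFAULT_ACTIVITY_CUTOFF_UM = 10.0
DEFAULT_MIN_CONFIDENCE = 5
DEFAULT_MIN_ACTIVES = 10


class PoolShortfallWarning(UserWarning):
    """Candidate pool exhausted before the requested sample size."""


class DegenerateClassWarning(UserWarning):
    """A class is too small or unbalanced for the requested operation."""


@dataclass(frozen=True)
class BioactivityRecord:
    """One measured or asserted compound-target data point.

    ``value_um`` is the activity concentration in micromolar (None for
    assertion-only inactives); ``confidence`` is a 0-9 curation score of
    how directly the assay maps to the protein target.
    """

    compound_id: str
    structure: str
    target_id: str
    activity_type: str
    value_um: float | None
    confidence: int
    reported_label: str = "unknown"


@dataclass(frozen=True)
class LabelledCompound:
    """A fingerprinted compound with its per-target label."""

    compound_id: str
    target_id: str
    fp: np.ndarray
    label: str  # "active" | "inactive"
    structure: str | None = None


@dataclass
class TargetClass:
    """One target's labelled training compounds.

    ``inactive_origin`` tags each inactive as ``"experimental"``
    (a measured/asserted inactive) or ``"sphere_excluded"`` (a putative
    inactive sampled from outside the actives' similarity sphere).
    """

    target_id: str
    active_ids: list[str]
    active_fps: np.ndarray
    inactive_ids: list[str]
    inactive_fps: np.ndarray
    inactive_origin: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def n_active(self) -> int:
        return len(self.active_ids)

    @property
    def n_inactive(self) -> int:
        return len(self.inactive_ids)

    @property
    def ratio(self) -> float:
        """Inactives per active (0 when there are no inactives)."""
        return self.n_inactive / self.n_active if self.n_active else 0.0

    def training_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Stacked fingerprints and binary labels (1=active, 0=inactive)."""
        fps = np.vstack([self.active_fps, self.inactive_fps])
        labels = np.concatenate(
            [np.ones(self.n_active, dtype=np.int8), np.zeros(self.n_inactive, dtype=np.int8)]
        )
        return fps, labels


@dataclass(frozen=True)
class ExclusionRadius:
    """Sphere-exclusion radius: Tanimoto cut-off and the coverage used."""

    tc: float
    coverage: float = DEFAULT_COVERAGE

    def __post_init__(self) -> None:
        if not 0.0 <= self.tc <= 1.0:
            raise ValueError(f"exclusion radius must be in [0, 1], got {self.tc}")


def label_record(
    rec: BioactivityRecord,
    activity_cutoff_um: float = DEFAULT_ACTIVITY_CUTOFF_UM,
    min_confidence: int = DEFAULT_MIN_CONFIDENCE,
) -> str:
    """Label a record ``"active"``, ``"inactive"`` or ``"discard"``.

    Active: quantitative endpoint (IC50/EC50/Ki/Kd) at or below the
    cutoff with sufficient curation confidence.  Inactive: the source
    asserts inactivity.  Everything else is discarded.
    """
    if (
        rec.activity_type in ACTIVITY_TYPES_QUANTITATIVE
        and rec.value_um is not None
        and rec.value_um <= activity_cutoff_um
        and rec.confidence >= min_confidence
    ):
        return "active"
    if rec.reported_label == "inactive":
        return "inactive"
    return "discard"


def assemble_classes(
    compounds: list[LabelledCompound],
    min_actives: int = DEFAULT_MIN_ACTIVES,
) -> tuple[list[TargetClass], dict]:
    """Group labelled compounds into per-target classes.

    Duplicate structures within one target collapse to a single
    instance; a compound labelled both active and inactive for the same
    target is kept as active only (actives are the curated side) and the
    conflict is counted in the report.  Targets with fewer than
    ``min_actives`` actives after deduplication are dropped.

    Returns the classes plus an assembly report
    (per-target counts, duplicates removed, conflicts, dropped targets).
    """
    by_target: dict[str, dict[str, list[LabelledCompound]]] = {}
    for c in compounds:
        slot = by_target.setdefault(c.target_id, {"active": [], "inactive": []})
        if c.label not in slot:
            raise ValueError(f"unknown label {c.label!r} for {c.compound_id!r}")
        slot[c.label].append(c)

    classes: list[TargetClass] = []
    report: dict = {"targets": {}, "dropped": []}
    for target_id in sorted(by_target):
        groups = by_target[target_id]
        seen: dict[object, str] = {}
        actives: list[LabelledCompound] = []
        n_dup = 0
        for c in groups["active"]:
            key = c.structure if c.structure is not None else c.fp.tobytes()
            if key in seen:
                n_dup += 1
                continue
            seen[key] = "active"
            actives.append(c)
        inactives: list[LabelledCompound] = []
        n_conflict = 0
        for c in groups["inactive"]:
            key = c.structure if c.structure is not None else c.fp.tobytes()
            if key in seen:
                if seen[key] == "active":
                    n_conflict += 1
                else:
                    n_dup += 1
                continue
            seen[key] = "inactive"
            inactives.append(c)

        entry = {
            "n_active": len(actives),
            "n_inactive": len(inactives),
            "duplicates_removed": n_dup,
            "label_conflicts_active_kept": n_conflict,
        }
        report["targets"][target_id] = entry
        if len(actives) < min_actives:
            report["dropped"].append(target_id)
            continue
        fp_len = actives[0].fp.shape[0]
        classes.append(
            TargetClass(
                target_id=target_id,
                active_ids=[c.compound_id for c in actives],
                active_fps=np.vstack([c.fp for c in actives]),
                inactive_ids=[c.compound_id for c in inactives],
                inactive_fps=(
                    np.vstack([c.fp for c in inactives])
                    if inactives
                    else np.empty((0, fp_len), dtype=np.uint8)
                ),
                inactive_origin=["experimental"] * len(inactives),
                provenance={"assembly": entry},
            )
        )
    return classes, report


def nn_distribution(active_fps: np.ndarray) -> np.ndarray:
    """Nearest-neighbour Tanimoto for each active within its class.

    For each active, the maximum similarity to any *other* active
    (self excluded).  Requires at least two actives.
    """
    fps = np.asarray(active_fps)
    if fps.ndim != 2 or len(fps) < 2:
        raise ValueError("nearest-neighbour distribution needs >= 2 actives")
    sim = pairwise_tanimoto(fps)
    np.fill_diagonal(sim, -np.inf)
    return sim.max(axis=1)


def select_exclusion_radius(
    nn_values: np.ndarray, coverage: float = DEFAULT_COVERAGE
) -> ExclusionRadius:
    """Empirical quantile of a nearest-neighbour similarity distribution.

    Returns the smallest observed Tc value ``t`` such that the fraction
    of values ``<= t`` is at least ``coverage`` (lower tie broken toward
    smaller t).
    """
    values = np.sort(np.asarray(nn_values, dtype=np.float64))
    if values.size == 0:
        raise ValueError("cannot select a radius from an empty distribution")
    if not 0.0 < coverage <= 1.0:
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    # fraction of values <= values[i] is (index of last equal value + 1)/n;
    # the smallest qualifying index is ceil(coverage*n) - 1.
    idx = int(np.ceil(coverage * values.size)) - 1
    return ExclusionRadius(tc=float(values[idx]), coverage=coverage)


def sphere_exclusion_sample(
    active_fps: np.ndarray,
    pool_ids: list[str],
    pool_fps: np.ndarray,
    radius: ExclusionRadius,
    n_required: int,
    seed: int,
) -> tuple[list[str], np.ndarray]:
    """Sample putative inactives from outside the actives' similarity sphere.

    Candidates are drawn uniformly at random without replacement
    (deterministically for a fixed seed); a candidate is accepted iff
    its maximum Tanimoto to every active is strictly below the radius.
    Stops after ``n_required`` acceptances or when the pool is
    exhausted, in which case a :class:`PoolShortfallWarning` is emitted
    and the accepted subset is returned.
    """
    if n_required < 0:
        raise ValueError("n_required must be >= 0")
    pool_fps = np.asarray(pool_fps)
    if len(pool_ids) != len(pool_fps):
        raise ValueError("pool ids and fingerprints differ in length")
    if n_required == 0 or len(pool_ids) == 0:
        if n_required > 0:
            warnings.warn(
                f"pool exhausted: 0 of {n_required} putative inactives sampled",
                PoolShortfallWarning,
            )
        return [], np.empty((0, pool_fps.shape[1] if pool_fps.ndim == 2 else 0), np.uint8)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool_ids))
    actives = np.asarray(active_fps)
    accepted: list[int] = []
    # evaluate candidates in draw order, chunked for speed
    chunk = 4096
    for start in range(0, len(order), chunk):
        idx = order[start : start + chunk]
        cand = pool_fps[idx].astype(np.int64)
        act = actives.astype(np.int64)
        inter = cand @ act.T
        union = cand.sum(axis=1)[:, None] + act.sum(axis=1)[None, :] - inter
        with np.errstate(invalid="ignore"):
            sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
        max_sim = sim.max(axis=1)
        for local, i in enumerate(idx):
            if max_sim[local] < radius.tc:
                accepted.append(int(i))
                if len(accepted) == n_required:
                    break
        if len(accepted) == n_required:
            break
    if len(accepted) < n_required:
        warnings.warn(
            f"pool exhausted: {len(accepted)} of {n_required} putative inactives sampled",
            PoolShortfallWarning,
        )
    ids = [pool_ids[i] for i in accepted]
    fps = pool_fps[accepted] if accepted else np.empty((0, pool_fps.shape[1]), np.uint8)
    return ids, fps


def balance_class(
    cls: TargetClass,
    pool_ids: list[str],
    pool_fps: np.ndarray,
    radius: ExclusionRadius,
    ratio: int = DEFAULT_INACTIVE_RATIO,
    seed: int = 0,
) -> TargetClass:
    """Bring a class to the target active:inactive ratio (default 1:100).

    Short classes are topped up with sphere-excluded putative inactives;
    oversized inactive sets are uniformly undersampled (seeded).
    Actives are never modified.
    """
    n_needed = ratio * cls.n_active
    prov = dict(cls.provenance)
    prov["balance"] = {"seed": seed, "ratio": ratio, "radius_tc": radius.tc,
                       "coverage": radius.coverage}
    if cls.n_inactive == n_needed:
        return TargetClass(
            cls.target_id, cls.active_ids, cls.active_fps,
            list(cls.inactive_ids), cls.inactive_fps, list(cls.inactive_origin), prov,
        )
    if cls.n_inactive > n_needed:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(cls.n_inactive, size=n_needed, replace=False))
        return TargetClass(
            cls.target_id, cls.active_ids, cls.active_fps,
            [cls.inactive_ids[i] for i in keep],
            cls.inactive_fps[keep],
            [cls.inactive_origin[i] for i in keep],
            prov,
        )
    existing = set(cls.inactive_ids) | set(cls.active_ids)
    mask = [i for i, pid in enumerate(pool_ids) if pid not in existing]
    ids, fps = sphere_exclusion_sample(
        cls.active_fps,
        [pool_ids[i] for i in mask],
        np.asarray(pool_fps)[mask] if mask else np.asarray(pool_fps)[:0],
        radius,
        n_required=n_needed - cls.n_inactive,
        seed=seed,
    )
    return TargetClass(
        cls.target_id, cls.active_ids, cls.active_fps,
        list(cls.inactive_ids) + ids,
        np.vstack([cls.inactive_fps, fps]) if len(fps) else cls.inactive_fps,
        list(cls.inactive_origin) + ["sphere_excluded"] * len(ids),
        prov,
    )


def class_tc(active_fps: np.ndarray, k: int = 5) -> float:
    """Mean intraclass similarity: per-active mean Tc of its top-k neighbours.

    For each active, average the similarity of its ``k`` most similar
    other actives (all others if the class is smaller than ``k + 1``),
    then average over actives.  A statistic of how tightly a class
    clusters in chemical space; 1.0 for an all-identical class.
    """
    fps = np.asarray(active_fps)
    if fps.ndim != 2 or len(fps) < 2:
        raise ValueError("class similarity needs >= 2 actives")
    sim = pairwise_tanimoto(fps)
    np.fill_diagonal(sim, -np.inf)
    kk = min(k, len(fps) - 1)
    top = np.sort(sim, axis=1)[:, -kk:]
    return float(top.mean())
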