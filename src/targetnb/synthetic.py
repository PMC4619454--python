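"""Synthetic fingerprint panels for testing every pipeline stage.

Real bioactivity corpora are large and licence-encumbered; the
generator here emulates their statistical shape directly at the
fingerprint level.  Each target class has a random seed bit pattern;
actives are density-preserving per-bit mutations of that pattern: each
seed on-bit is lost with the mutation rate and replaced in expectation
by a random background bit, so the expected on-bit count is the same
for every mutation rate.  Intraclass similarity therefore decreases
strictly monotonically from 1 (rate 0) down to background similarity
(rate 1), and inactives drawn from the background distribution share
the actives' bit density, so class separability comes from pattern
structure rather than bit count.  A ground-truth compound-to-target
map and a shared background pool (for sphere-exclusion sampling) come
with each panel.

Compounds are fingerprints directly -- no SMILES round trip -- for
speed and exact control of similarity; a small hard-coded SMILES
fixture covers the structure-handling path separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .training import TargetClass

DEFAULT_SEED_DENSITY = 0.05


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of a synthetic target panel.

    ``intraclass_mutation_rate`` is the probability that a seed on-bit
    is lost per compound (0 => all actives identical; 1 => actives are
    background noise); each lost signal bit is compensated by random
    background bits so the expected density never changes.
    ``interclass_overlap`` is the fraction of seed bits shared between
    targets (1 => exchangeable classes).  ``inactive_mutation_rate``,
    when set, draws the experimental inactives as mutations of the
    class seed instead of from the background, emulating measured
    inactives that share scaffolds with the actives.
    """

    n_targets: int = 20
    actives_per_target: int = 50
    inactive_ratio: int = 100
    fp_length: int = 2048
    intraclass_mutation_rate: float = 0.05
    interclass_overlap: float = 0.0
    seed: int = 0
    seed_density: float = DEFAULT_SEED_DENSITY
    inactive_mutation_rate: float | None = None

    def __post_init__(self) -> None:
        for name in ("intraclass_mutation_rate", "interclass_overlap", "seed_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.n_targets, self.actives_per_target, self.fp_length) < 1:
            raise ValueError("counts must be >= 1")
        if self.inactive_ratio < 0:
            raise ValueError("inactive_ratio must be >= 0")

    @property
    def background_density(self) -> float:
        """Expected on-bit fraction, identical for actives and background."""
        return self.seed_density


def _class_rng(spec: PanelSpec, target_index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, target_index, stream])
    )


def _shared_seed_bits(spec: PanelSpec) -> np.ndarray:
    """Seed bits shared across all classes (interclass overlap)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 10**6]))
    n_on = max(1, round(spec.seed_density * spec.fp_length))
    n_shared = round(spec.interclass_overlap * n_on)
    return rng.choice(spec.fp_length, size=n_shared, replace=False)


def _class_seed_pattern(spec: PanelSpec, target_index: int) -> np.ndarray:
    n_on = max(1, round(spec.seed_density * spec.fp_length))
    shared = _shared_seed_bits(spec)
    rng = _class_rng(spec, target_index, stream=1)
    remaining = np.setdiff1d(np.arange(spec.fp_length), shared)
    own = rng.choice(remaining, size=n_on - len(shared), replace=False)
    pattern = np.zeros(spec.fp_length, dtype=np.uint8)
    pattern[shared] = 1
    pattern[own] = 1
    return pattern


def _mutate(pattern: np.ndarray, rate: float, n: int,
            rng: np.random.Generator) -> np.ndarray:
    """Density-preserving mutation of a seed pattern.

    On-bits are lost with probability ``rate``, and every position
    independently gains a noise bit at the compensating rate
    g = rate*s / (1 - s*(1 - rate)) (s = pattern density), so the
    expected on-bit count equals the pattern's at every rate and
    rate 1 is exactly the background distribution.
    """
    on = pattern.astype(bool)
    s = on.mean()
    gain = rate * s / (1.0 - s * (1.0 - rate)) if s < 1.0 else 0.0
    kept = on[None, :] & (rng.random((n, pattern.shape[0])) >= rate)
    noise = rng.random((n, pattern.shape[0])) < gain
    return (kept | noise).astype(np.uint8)


def background_fps(spec: PanelSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Background compounds: iid bits at the actives' expected density."""
    return (rng.random((n, spec.fp_length)) < spec.background_density).astype(np.uint8)


def generate_class(spec: PanelSpec, target_index: int) -> TargetClass:
    """One synthetic target class; deterministic for a fixed spec seed.

    Expected intraclass similarity decreases as the mutation rate
    increases: at rate 0 all actives are identical (class_tc = 1); at
    rate 0.5 actives are indistinguishable from background.
    """
    pattern = _class_seed_pattern(spec, target_index)
    rng = _class_rng(spec, target_index, stream=2)
    actives = _mutate(pattern, spec.intraclass_mutation_rate,
                      spec.actives_per_target, rng)
    n_inact = spec.inactive_ratio * spec.actives_per_target
    if spec.inactive_mutation_rate is not None:
        inactives = _mutate(pattern, spec.inactive_mutation_rate, n_inact, rng)
    else:
        inactives = background_fps(spec, n_inact, rng)
    tid = f"T{target_index:03d}"
    return TargetClass(
        target_id=tid,
        active_ids=[f"{tid}_A{i:05d}" for i in range(len(actives))],
        active_fps=actives,
        inactive_ids=[f"{tid}_I{i:05d}" for i in range(len(inactives))],
        inactive_fps=inactives,
        inactive_origin=["experimental"] * len(inactives),
        provenance={"synthetic": True, "seed": spec.seed, "target_index": target_index,
                    "mutation_rate": spec.intraclass_mutation_rate},
    )


def generate_panel(
    spec: PanelSpec, pool_size: int = 0
) -> tuple[list[TargetClass], dict[str, str], tuple[list[str], np.ndarray]]:
    """Full panel: classes, ground-truth compound->target map, background pool.

    The pool (``pool_size`` extra background compounds) is disjoint by
    id from every class and suitable as a sphere-exclusion candidate
    set.
    """
    classes = [generate_class(spec, i) for i in range(spec.n_targets)]
    truth = {cid: cls.target_id for cls in classes for cid in cls.active_ids}
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 10**6 + 1]))
    pool_fps = background_fps(spec, pool_size, rng)
    pool_ids = [f"POOL_{i:06d}" for i in range(pool_size)]
    return classes, truth, (pool_ids, pool_fps)


#: Curated drug-like structures for end-to-end smoke tests, including
#: deliberate filter failures: a salt (standardizes to its largest
#: fragment), sub-100 Da molecules, an organofluorine and an
#: organoboron (disallowed elements), and a >900 Da macrocycle.
SMILES_FIXTURE: list[tuple[str, str]] = [
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("ibuprofen", "CC(C)Cc1ccc(C(C)C(=O)O)cc1"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("naproxen", "COc1ccc2cc(C(C)C(=O)O)ccc2c1"),
    ("diclofenac", "O=C(O)Cc1ccccc1Nc1c(Cl)cccc1Cl"),
    ("chlorpromazine", "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21"),
    ("propranolol", "CC(C)NCC(O)COc1cccc2ccccc12"),
    ("atenolol", "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1"),
    ("warfarin", "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O"),
    ("diazepam", "CN1c2ccc(Cl)cc2C(c2ccccc2)=NCC1=O"),
    ("imatinib", "Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1"),
    ("quinine", "C=CC1CN2CCC1CC2C(O)c1ccnc2ccc(OC)cc12"),
    ("ketamine", "CNC1(c2ccccc2Cl)CCCCC1=O"),
    ("sertraline_hcl_salt", "CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc21.Cl"),
    ("ethanol_low_mw", "CCO"),
    ("glycine_low_mw", "NCC(=O)O"),
    ("fluoxetine_organofluorine", "CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1"),
    ("tolylboronic_organoboron", "Cc1ccc(B(O)O)cc1"),
    ("cyclosporin_high_mw",
     "CCC1C(=O)N(C)CC(=O)N(C)C(C(C)C)C(=O)N(C)C(CC(C)C)C(=O)NC(C(C)C)C(=O)N(C)C(CC(C)C)"
     "C(=O)NC(C)C(=O)NC(C)C(=O)N(C)C(CC(C)C)C(=O)N(C)C(CC(C)C)C(=O)N(C)C(C(C)CC=CC)C1=O"),
]


def smiles_fixture() -> list[tuple[str, str]]:
    """(id, SMILES) pairs spanning the structure-filter boundaries."""
    return list(SMILES_FIXTURE)
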