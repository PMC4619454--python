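"""Distance-based applicability domain (AD) assessment.

A prediction is only as trustworthy as the query's proximity to the
chemistry the model was trained on.  The AD score here is the maximum
Tanimoto similarity of the query to the target's training compounds
(the actives by default), mapped onto a reliability band:

    reliable    nn_tc >= 0.3   probabilities consistently dependable
    caution     0.1 - 0.3      grey area; scores vary widely
    low         0.03 - 0.1     mostly unreliable, not always worthless
    unreliable  < 0.03         training data does not cover the query
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import bulk_tanimoto

BANDS = ("reliable", "caution", "low", "unreliable")


@dataclass(frozen=True)
class ADCutoffs:
    """Similarity cut-offs separating the reliability bands."""

    reliable: float = 0.3
    caution: float = 0.1
    low: float = 0.03

    def __post_init__(self) -> None:
        if not 0.0 <= self.low <= self.caution <= self.reliable <= 1.0:
            raise ValueError("AD cut-offs must be ordered in [0, 1]")


DEFAULT_CUTOFFS = ADCutoffs()


@dataclass(frozen=True)
class ADAssessment:
    compound_id: str
    target_id: str
    nn_tc: float
    band: str


def query_nn_similarity(fp: np.ndarray, training_fps: np.ndarray) -> float:
    """Maximum Tanimoto of the query to any training compound."""
    training_fps = np.asarray(training_fps)
    if training_fps.ndim != 2 or len(training_fps) == 0:
        raise ValueError("training set is empty")
    return float(bulk_tanimoto(np.asarray(fp), training_fps).max())


def ad_band(nn_tc: float, cutoffs: ADCutoffs = DEFAULT_CUTOFFS) -> str:
    """Reliability band for a nearest-neighbour similarity."""
    if not 0.0 <= nn_tc <= 1.0:
        raise ValueError(f"nn_tc must be in [0, 1], got {nn_tc}")
    if nn_tc >= cutoffs.reliable:
        return "reliable"
    if nn_tc >= cutoffs.caution:
        return "caution"
    if nn_tc >= cutoffs.low:
        return "low"
    return "unreliable"


def assess(
    fp: np.ndarray,
    training_fps: np.ndarray,
    compound_id: str = "",
    target_id: str = "",
    cutoffs: ADCutoffs = DEFAULT_CUTOFFS,
) -> ADAssessment:
    """Full AD assessment of one query against one target's training set."""
    nn = query_nn_similarity(fp, training_fps)
    return ADAssessment(compound_id=compound_id, target_id=target_id,
                        nn_tc=nn, band=ad_band(nn, cutoffs))
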