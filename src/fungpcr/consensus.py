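"""Three-model consensus call for novel GPCR candidates.

Each candidate carries confidence scores from three independent
classifiers (ProteInfer, DeepFRI, and the 1D-CNN of this package). A
candidate is consensus-positive when every score strictly exceeds its
model-specific threshold (0.8 / 0.2 / 0.9); the consensus score is the
plain sum of the three, so positives land strictly above 1.9 and at most
at 3.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ScoreTriple", "ConsensusCall", "DEFAULT_THRESHOLDS",
           "consensus_call", "consensus_table", "bin_report", "SCORE_BINS"]

DEFAULT_THRESHOLDS = (0.8, 0.2, 0.9)  # proteinfer, deepfri, cnn
SCORE_BINS = (1.9, 2.0, 2.25, 2.5, 3.0)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoreTriple:
    proteinfer: float
    deepfri: float
    cnn: float

    def __post_init__(self) -> None:
        for name in ("proteinfer", "deepfri", "cnn"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} score {v} outside [0, 1]")


@dataclass(frozen=True)
class ConsensusCall:
    positive: bool
    consensus_score: float

    def __post_init__(self) -> None:
        if self.positive and not self.consensus_score > 1.9:
            raise ValueError("a positive call implies consensus score > 1.9")
        if not 0.0 <= self.consensus_score <= 3.0:
            raise ValueError("consensus score must lie in [0, 3]")


def consensus_call(
    triple: ScoreTriple,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> ConsensusCall:
    """Conjunction of three strict per-model thresholds; score is the sum."""
    positive = (triple.proteinfer > thresholds[0]
                and triple.deepfri > thresholds[1]
                and triple.cnn > thresholds[2])
    total = triple.proteinfer + triple.deepfri + triple.cnn
    return ConsensusCall(positive=positive, consensus_score=total)


def consensus_table(
    proteinfer: Mapping[str, float],
    deepfri: Mapping[str, float],
    cnn: Mapping[str, float],
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    species_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Combine three id -> score tables into a consensus table.

    Sequences missing from any table are excluded and logged. Columns:
    ``seq_id, species, proteinfer, deepfri, cnn, consensus_score, positive``.
    """
    species_map = species_map or {}
    shared = sorted(set(proteinfer) & set(deepfri) & set(cnn))
    dropped = (set(proteinfer) | set(deepfri) | set(cnn)) - set(shared)
    for seq_id in sorted(dropped):
        logger.warning("sequence %s missing a model score; excluded", seq_id)
    rows = []
    for seq_id in shared:
        t = ScoreTriple(proteinfer[seq_id], deepfri[seq_id], cnn[seq_id])
        call = consensus_call(t, thresholds)
        rows.append((seq_id, species_map.get(seq_id, ""), t.proteinfer,
                     t.deepfri, t.cnn, call.consensus_score, call.positive))
    return pd.DataFrame(rows, columns=[
        "seq_id", "species", "proteinfer", "deepfri", "cnn",
        "consensus_score", "positive"])


def bin_report(calls: pd.DataFrame, by: str | None = None) -> pd.DataFrame:
    """Histogram of consensus-positive scores over the standard bins
    [1.9, 2.0), [2.0, 2.25), [2.25, 2.5), [2.5, 3.0]; optionally split by a
    grouping column (species/order). Counts sum to the number of positives.
    """
    pos = calls[calls["positive"]]
    edges = list(SCORE_BINS)
    labels = [f"[{lo},{hi})" for lo, hi in zip(edges[:-1], edges[1:])]
    if pos.empty:
        return pd.DataFrame(columns=labels)
    binned = pd.cut(pos["consensus_score"], bins=edges, labels=labels,
                    right=False, include_lowest=True)
    # the top bin is closed at 3.0
    at_top = pos["consensus_score"] == edges[-1]
    binned = binned.astype(object)
    binned[at_top] = labels[-1]
    if by is None:
        counts = pd.Series(binned).value_counts().reindex(labels, fill_value=0)
        return counts.to_frame().T
    frame = pos.assign(_bin=binned)
    return (frame.groupby(by)["_bin"].value_counts().unstack(fill_value=0)
            .reindex(columns=labels, fill_value=0))
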