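"""Transmembrane-helix topology: counting, per-class acceptance rules,
membrane-orientation checks, and a hydropathy fallback predictor.

A GPCR threads the membrane seven times with an extracellular N-terminus
and an intracellular C-terminus. Topology here is an ordered tiling of the
sequence into ``inside`` / ``TMhelix`` / ``outside`` segments, as emitted
by membrane-topology predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TMTopology",
    "TmhRule",
    "FUNGAL_DEFAULT_RULE",
    "WIDE_HELIX_RULE",
    "MAMMALIAN_SCREEN_RULE",
    "NOVEL_SCREEN_RULE",
    "NOVEL_CNN_RULE",
    "count_tmh",
    "check_orientation",
    "tmh_accept",
    "predict_tmh_fallback",
    "KYTE_DOOLITTLE",
]

SEGMENT_LABELS = ("inside", "TMhelix", "outside")

#: Kyte-Doolittle hydropathy index per residue.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass(frozen=True)
class TMTopology:
    """Ordered membrane-topology segments over one sequence.

    ``segments`` are ``(label, start, end)`` with 1-based inclusive
    coordinates tiling ``1..seq_len`` without gaps or overlaps; two TMhelix
    segments are never adjacent.
    """

    segments: tuple[tuple[str, int, int], ...]
    seq_len: int

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("topology must contain at least one segment")
        pos = 1
        prev_label = None
        for label, start, end in self.segments:
            if label not in SEGMENT_LABELS:
                raise ValueError(f"unknown segment label {label!r}")
            if start != pos:
                raise ValueError(
                    f"segments not contiguous: expected start {pos}, "
                    f"got {start} ({label})"
                )
            if end < start:
                raise ValueError(f"segment {label} has end {end} < start {start}")
            if label == "TMhelix" and prev_label == "TMhelix":
                raise ValueError("two adjacent TMhelix segments")
            pos = end + 1
            prev_label = label
        if pos - 1 != self.seq_len:
            raise ValueError(
                f"segments cover 1..{pos - 1} but seq_len is {self.seq_len}"
            )

    @classmethod
    def from_segments(
        cls, segments: Iterable[tuple[str, int, int]],
        seq_len: int | None = None,
    ) -> "TMTopology":
        segs = tuple((str(l), int(s), int(e)) for l, s, e in segments)
        if seq_len is None:
            seq_len = segs[-1][2] if segs else 0
        return cls(segments=segs, seq_len=seq_len)

    @property
    def n_helices(self) -> int:
        return sum(1 for label, _, _ in self.segments if label == "TMhelix")

    @property
    def first_label(self) -> str:
        return self.segments[0][0]

    @property
    def last_label(self) -> str:
        return self.segments[-1][0]


@dataclass(frozen=True)
class TmhRule:
    """Set of acceptable transmembrane-helix counts for one screen context."""

    name: str
    allowed: frozenset[int]

    def __post_init__(self) -> None:
        if not self.allowed:
            raise ValueError("allowed helix-count set must be non-empty")

    @classmethod
    def from_range(cls, name: str, lo: int, hi: int) -> "TmhRule":
        return cls(name=name, allowed=frozenset(range(lo, hi + 1)))


#: 6-7 helices: the default gate for the 14 fungal classes (tolerates the
#: predictor occasionally under-calling one helix).
FUNGAL_DEFAULT_RULE = TmhRule.from_range("fungal_default", 6, 7)
#: 7-9 helices: classes whose members carry up to nine helices.
WIDE_HELIX_RULE = TmhRule.from_range("wide_helix", 7, 9)
#: exactly 7: mammalian-homolog screen (classes 15-17).
MAMMALIAN_SCREEN_RULE = TmhRule(name="mammalian_screen", allowed=frozenset({7}))
#: exactly 7: candidate pool ahead of clustering in the novel-receptor screen.
NOVEL_SCREEN_RULE = TmhRule(name="novel_screen", allowed=frozenset({7}))
#: 7-9: the eligible query universe for CNN scoring.
NOVEL_CNN_RULE = TmhRule.from_range("novel_cnn", 7, 9)


def count_tmh(top: TMTopology) -> int:
    """Number of transmembrane helices in a topology."""
    return top.n_helices


def check_orientation(top: TMTopology) -> bool:
    """True iff the topology has an extracellular N-terminus and an
    intracellular C-terminus (first segment outside, last segment inside).

    Raises ``ValueError`` on zero-helix topologies, where orientation is
    undefined.
    """
    if top.n_helices == 0:
        raise ValueError("orientation undefined for a topology with no helices")
    return top.first_label == "outside" and top.last_label == "inside"


def tmh_accept(n: int, rule: TmhRule) -> bool:
    """Whether a helix count ``n`` satisfies a screen's acceptance rule."""
    if n < 0:
        raise ValueError("helix count must be >= 0")
    return n in rule.allowed


def predict_tmh_fallback(
    seq: str,
    window: int = 19,
    kd_threshold: float = 1.6,
    min_run: int = 15,
    merge_gap: int = 5,
    n_term_side: str = "outside",
) -> TMTopology:
    """Hydropathy-based transmembrane-helix prediction.

    Slides a ``window``-wide Kyte-Doolittle mean over the sequence; maximal
    runs of window centers above ``kd_threshold`` that are at least
    ``min_run`` long (runs separated by fewer than ``merge_gap`` positions
    are merged first) become TMhelix segments. Flanking regions alternate
    between sides starting from ``n_term_side`` at the N-terminus.

    This is a deliberately simple stand-in for a dedicated topology
    predictor: it recovers designed helices in synthetic sequences but has
    no notion of membrane insertion energetics or signal peptides, and it
    cannot infer sidedness from sequence (``n_term_side`` declares it).
    """
    n = len(seq)
    if n < window:
        raise ValueError(f"sequence length {n} shorter than window {window}")
    if n_term_side not in ("inside", "outside"):
        raise ValueError("n_term_side must be 'inside' or 'outside'")

    kd = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in seq], dtype=float)
    means = np.convolve(kd, np.ones(window) / window, mode="valid")
    above = means > kd_threshold  # index i = window starting at residue i+1

    # maximal runs of super-threshold windows
    runs: list[tuple[int, int]] = []  # 0-based [start, end] in window index
    i = 0
    m = len(above)
    while i < m:
        if above[i]:
            j = i
            while j + 1 < m and above[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    # merge runs separated by a small gap
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < merge_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    helices = [
        # window run [a, b] covers residues a+1 .. b+window (1-based); take
        # the run's central `window`-or-longer span as the helix
        (a + 1 + window // 2, b + window - window // 2)
        for a, b in merged
        if b - a + 1 >= min_run
    ]
    helices = [(max(1, s), min(n, e)) for s, e in helices if s <= e]

    other = {"inside": "outside", "outside": "inside"}
    segments: list[tuple[str, int, int]] = []
    side = n_term_side
    pos = 1
    for start, end in helices:
        if start > pos:
            segments.append((side, pos, start - 1))
        elif segments and segments[-1][0] == "TMhelix":
            # keep helices non-adjacent by inserting a 0-length-impossible
            # separator: shrink the new helix by one to leave a loop residue
            segments.append((side, start, start))
            start += 1
        segments.append(("TMhelix", start, end))
        side = other[side]
        pos = end + 1
    if pos <= n:
        segments.append((side, pos, n))
    elif segments[-1][0] == "TMhelix":
        # topology must not end mid-membrane; trim one residue for the tail
        label, s, e = segments.pop()
        segments.append((label, s, e - 1))
        segments.append((side, e, n))
    if not segments:
        segments = [(n_term_side, 1, n)]
    return TMTopology.from_segments(segments, seq_len=n)
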