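"""Term enrichment in gene sets and receptor/BGC co-location.

Enrichment: per-term 2x2 tables (foreground vs background-only, with vs
without term) tested with Fisher's exact two-sided test, adjusted across
terms with Benjamini-Hochberg.

Co-location: a receptor gene is co-located with a biosynthetic gene
cluster (BGC) when their intervals overlap by at least one base on the
same scaffold (1-based inclusive coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "enrich", "bgc_colocate", "GenomicInterval"]


@dataclass(frozen=True)
class GenomicInterval:
    scaffold: str
    start: int
    end: int
    feature_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.feature_id}: start {self.start} > end {self.end}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.scaffold == other.scaffold
                and self.start <= other.end and other.start <= self.end)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    a: int  # foreground, with term
    b: int  # foreground, without term
    c: int  # background-only, with term
    d: int  # background-only, without term
    odds_ratio: float
    p: float
    q: float


def enrich(
    foreground: Iterable[str],
    background: Iterable[str],
    terms: Mapping[str, set[str] | Sequence[str]],
) -> list[EnrichmentResult]:
    """Term enrichment of ``foreground`` genes against ``background``.

    ``terms`` maps gene id to its term ids (Pfam accessions or GO ids).
    Every term occurring on a background gene is tested; results are
    sorted by adjusted q-value, then p, then term. The foreground must be
    a non-empty subset of the background.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg:
        raise ValueError("empty foreground")
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")

    genes_by_term: dict[str, set[str]] = {}
    for gene in bg:
        for term in terms.get(gene, ()):
            genes_by_term.setdefault(term, set()).add(gene)

    rest = bg - fg
    rows = []
    for term, genes in sorted(genes_by_term.items()):
        a = len(genes & fg)
        b = len(fg) - a
        c = len(genes & rest)
        d = len(rest) - c
        odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((term, a, b, c, d, float(odds), float(p)))
    if not rows:
        return []
    pvals = [r[6] for r in rows]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [EnrichmentResult(*row, q=float(q))
               for row, q in zip(rows, qvals)]
    return sorted(results, key=lambda r: (r.q, r.p, r.term))


def _to_intervals(obj) -> list[GenomicInterval]:
    if isinstance(obj, pd.DataFrame):
        return [GenomicInterval(str(r.scaffold), int(r.start), int(r.end),
                                str(r.feature_id))
                for r in obj.itertuples(index=False)]
    return list(obj)


def bgc_colocate(
    gpcr_intervals,
    bgc_intervals,
    core_gene_intervals=None,
    proximity_bp: int = 10_000,
) -> pd.DataFrame:
    """Receptor/BGC co-location table.

    One row per receptor interval with columns ``feature_id, scaffold,
    colocated, bgc_id, nearest_core_gene, core_gene_distance``. A receptor
    is co-located when its interval shares >= 1 bp with a BGC interval on
    the same scaffold (touching at a single position counts). When core
    gene intervals (e.g. PKS/NRPS genes) are supplied, the nearest one on
    the same scaffold is reported with its distance (0 if overlapping;
    NaN/None beyond ``proximity_bp``).
    """
    gpcrs = _to_intervals(gpcr_intervals)
    bgcs = _to_intervals(bgc_intervals)
    cores = _to_intervals(core_gene_intervals) if core_gene_intervals is not None else []

    rows = []
    for g in gpcrs:
        hit = next((b for b in bgcs if g.overlaps(b)), None)
        nearest, distance = None, None
        candidates = [c for c in cores if c.scaffold == g.scaffold]
        if candidates:
            def gap(c):
                if g.overlaps(c):
                    return 0
                return (c.start - g.end if c.start > g.end
                        else g.start - c.end)
            best = min(candidates, key=gap)
            d = gap(best)
            if d <= proximity_bp:
                nearest, distance = best.feature_id, d
        rows.append((g.feature_id, g.scaffold, hit is not None,
                     hit.feature_id if hit else None, nearest, distance))
    return pd.DataFrame(rows, columns=[
        "feature_id", "scaffold", "colocated", "bgc_id",
        "nearest_core_gene", "core_gene_distance"])
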