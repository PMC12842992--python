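"""The GPCR identification cascade and its summary statistics.

Seventeen receptor classes are recognized: fourteen fungal classes (each
with a class-diagnostic Pfam domain, e.g. STE2/PF02116 for class 1,
CFEM/PF05730 for the Pth11-like class 14) plus three mammalian-homolog
classes (Rhodopsin 15, Glutamate 16, Frizzled 17).

The cascade for the fungal classes: a BLAST gate (E-value and dual
coverage), an HMM gate (per-class profile hits), transmembrane-helix count
and orientation gates, then Pfam-domain consistency confirmation. The
mammalian screen instead starts from family Pfam domains and requires
exactly seven helices with the canonical orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import BlastHit, HmmHit, PfamAnnotation
from .topology import (
    FUNGAL_DEFAULT_RULE,
    MAMMALIAN_SCREEN_RULE,
    WIDE_HELIX_RULE,
    TMTopology,
    TmhRule,
    check_orientation,
    count_tmh,
    tmh_accept,
)

__all__ = [
    "GpcrClass",
    "CLASS_TABLE",
    "Classification",
    "blast_gate",
    "hmm_gate",
    "assign_class",
    "screen_mammalian",
    "pfam_consistency_report",
    "consistency_percentage",
    "abundance_matrix",
    "class_proportions",
]


@dataclass(frozen=True)
class GpcrClass:
    class_id: int
    name: str
    domains: tuple[str, ...]         # class-diagnostic Pfam domain name(s)
    accessions: tuple[str, ...]      # matching PFxxxxx accession(s)
    tmh_rule: TmhRule


def _fungal(class_id, name, domain, acc, wide=False):
    rule = WIDE_HELIX_RULE if wide else FUNGAL_DEFAULT_RULE
    return GpcrClass(class_id, name, (domain,), (acc,), rule)


#: The 17-class table: class-diagnostic domain(s) and helix-count rule.
#: Classes 9 and 11 admit 7-9 helices (members of these classes carry up to
#: nine); the other fungal classes admit 6-7; the mammalian-homolog classes
#: require exactly 7.
CLASS_TABLE: dict[int, GpcrClass] = {c.class_id: c for c in [
    _fungal(1, "Ste2-like", "STE2", "PF02116"),
    _fungal(2, "Ste3-like", "STE3", "PF02076"),
    _fungal(3, "Git3-like", "Git3", "PF11710"),
    _fungal(4, "PQ-loop", "PQ-loop", "PF04193"),
    _fungal(5, "cAMP receptor-like", "Dicty_CAR", "PF05462"),
    _fungal(6, "RGS-fused", "RGS", "PF00615"),
    _fungal(7, "Secretin-like", "7tm_2", "PF00002"),
    _fungal(8, "HlyIII-related", "HlyIII", "PF03006"),
    _fungal(9, "Microbial opsin", "Bac_rhodopsin", "PF01036", wide=True),
    _fungal(10, "Lung 7TM-like", "Lung_7-TM_R", "PF06814"),
    _fungal(11, "GprK-like", "ABA_GPCR", "PF12430", wide=True),
    _fungal(12, "DUF3112", "DUF3112", "PF11309"),
    _fungal(13, "Ost-alpha-like", "Solute_trans_a", "PF03619"),
    _fungal(14, "Pth11-like", "CFEM", "PF05730"),
    GpcrClass(15, "Rhodopsin", ("7tm_1",), ("PF00001",), MAMMALIAN_SCREEN_RULE),
    GpcrClass(16, "Glutamate", ("7tm_3",), ("PF00003",), MAMMALIAN_SCREEN_RULE),
    GpcrClass(17, "Frizzled", ("Frizzled", "Fz"), ("PF01534", "PF01392"),
              MAMMALIAN_SCREEN_RULE),
]}

#: Mammalian family domains screened but expected absent in fungi.
ABSENT_MAMMALIAN_DOMAINS = ("TAS2R", "GAIN", "GPS", "hEGF", "EGF_CA",
                            "Calx-beta", "Cadher")


@dataclass
class Classification:
    """Per-sequence cascade outcome with full evidence trail."""

    seq_id: str
    class_id: int | None = None
    species: str = ""
    blast_pass: bool = False
    hmm_pass: bool = False
    tmh_pass: bool = False
    topology_pass: bool = False
    pfam_domains: tuple[str, ...] = ()
    pfam_consistent: str = "no_domain"   # yes | no | no_domain
    best_evalue: float | None = None
    candidate_note: str = ""

    def __post_init__(self) -> None:
        if self.class_id is not None and not (
                self.tmh_pass and self.topology_pass):
            raise ValueError(
                f"{self.seq_id}: a class assignment requires passing "
                "helix-count and orientation gates"
            )


def blast_gate(
    hits: Iterable[BlastHit], emax: float = 1e-5, min_cov: float = 0.75,
) -> list[BlastHit]:
    """Keep hits with E-value < ``emax`` and > ``min_cov`` coverage of both
    the query and the subject (strict inequalities on all three)."""
    kept = []
    for h in hits:
        if h.qlen <= 0 or h.slen <= 0:
            raise ValueError(f"non-positive length on hit {h.qid}->{h.sid}")
        if (h.evalue < emax
                and h.query_coverage > min_cov
                and h.subject_coverage > min_cov):
            kept.append(h)
    return kept


def hmm_gate(hits: Iterable[HmmHit], emax: float = 1e-5) -> list[HmmHit]:
    """Keep HMM hits with E-value strictly below ``emax``."""
    return [h for h in hits if h.evalue < emax]


def assign_class(
    seq_id: str,
    hmm_hits: Sequence[HmmHit],
    topology: TMTopology,
    class_table: Mapping[int, GpcrClass] = CLASS_TABLE,
    species: str = "",
) -> Classification:
    """Assign one of the fourteen fungal classes from gated HMM evidence.

    Among classes with a surviving hit whose helix-count rule accepts the
    topology and whose orientation check passes, the smallest E-value wins;
    ties break on larger bit score, then smaller class index. Returns a
    class-less ``Classification`` (with evidence flags) when nothing
    qualifies.
    """
    n = count_tmh(topology)
    oriented = check_orientation(topology) if n > 0 else False
    mine = [h for h in hmm_hits if h.target_id == seq_id]

    candidates = []
    any_tmh_pass = False
    for h in mine:
        cls = class_table[h.class_id]
        if tmh_accept(n, cls.tmh_rule):
            any_tmh_pass = True
            if oriented:
                candidates.append(h)
    if not candidates:
        return Classification(
            seq_id=seq_id, species=species, hmm_pass=bool(mine),
            tmh_pass=any_tmh_pass, topology_pass=oriented,
            best_evalue=min((h.evalue for h in mine), default=None),
        )
    best = min(candidates, key=lambda h: (h.evalue, -h.score, h.class_id))
    return Classification(
        seq_id=seq_id, class_id=best.class_id, species=species,
        hmm_pass=True, tmh_pass=True, topology_pass=True,
        best_evalue=best.evalue,
    )


_MAMMALIAN_DOMAIN_TO_CLASS = {"7tm_1": 15, "7tm_3": 16,
                              "Frizzled": 17, "Fz": 17}


def screen_mammalian(
    annotations: Iterable[PfamAnnotation],
    topologies: Mapping[str, TMTopology],
    class_table: Mapping[int, GpcrClass] = CLASS_TABLE,
    emax: float = 1e-5,
    species_map: Mapping[str, str] | None = None,
) -> list[Classification]:
    """Mammalian-homolog screen: family Pfam domain below ``emax`` plus
    exactly seven helices with the canonical orientation.

    Rhodopsin (7tm_1), Glutamate (7tm_3) and Frizzled (Frizzled/Fz) map to
    classes 15-17. Taste2 (TAS2R) and Adhesion-family domains are screened
    and recorded as candidates but never assigned a class — these families
    appear absent in fungi.
    """
    species_map = species_map or {}
    by_seq: dict[str, list[PfamAnnotation]] = {}
    for a in annotations:
        by_seq.setdefault(a.seq_id, []).append(a)

    results: list[Classification] = []
    for seq_id, annots in by_seq.items():
        relevant = [
            a for a in annots
            if a.evalue < emax and (
                a.domain_name in _MAMMALIAN_DOMAIN_TO_CLASS
                or a.domain_name in ABSENT_MAMMALIAN_DOMAINS)
        ]
        if not relevant:
            continue
        top = topologies.get(seq_id)
        if top is None:
            continue
        n = count_tmh(top)
        tmh_ok = tmh_accept(n, MAMMALIAN_SCREEN_RULE)
        oriented = check_orientation(top) if n > 0 else False
        domains = tuple(a.domain_name for a in annots)
        species = species_map.get(seq_id, "")

        assignable = [a for a in relevant
                      if a.domain_name in _MAMMALIAN_DOMAIN_TO_CLASS]
        absent_family = [a for a in relevant
                         if a.domain_name in ABSENT_MAMMALIAN_DOMAINS]
        if assignable and tmh_ok and oriented:
            best = min(assignable, key=lambda a: a.evalue)
            cid = _MAMMALIAN_DOMAIN_TO_CLASS[best.domain_name]
            results.append(Classification(
                seq_id=seq_id, class_id=cid, species=species,
                tmh_pass=True, topology_pass=True,
                pfam_domains=domains, pfam_consistent="yes",
                best_evalue=best.evalue,
            ))
        else:
            note = ""
            if absent_family and not assignable:
                fam = ("Taste2" if any(a.domain_name == "TAS2R"
                                       for a in absent_family) else "Adhesion")
                note = f"{fam} candidate (family absent in fungi)"
            results.append(Classification(
                seq_id=seq_id, species=species, tmh_pass=tmh_ok,
                topology_pass=oriented, pfam_domains=domains,
                pfam_consistent="no",
                best_evalue=min(a.evalue for a in relevant),
                candidate_note=note,
            ))
    return results


def annotate_pfam_consistency(
    classifications: Iterable[Classification],
    annotations: Iterable[PfamAnnotation],
    class_table: Mapping[int, GpcrClass] = CLASS_TABLE,
) -> list[Classification]:
    """Attach Pfam domains to classifications and flag consistency.

    A classified sequence is consistent when at least one of its domains is
    the class-diagnostic domain of its assigned class; extra unrelated
    domains do not penalize. Sequences without any domain annotation are
    flagged ``no_domain``.
    """
    by_seq: dict[str, list[str]] = {}
    for a in annotations:
        by_seq.setdefault(a.seq_id, []).append(a.domain_name)
    out = []
    for c in classifications:
        domains = tuple(by_seq.get(c.seq_id, ()))
        if not domains:
            flag = "no_domain"
        elif c.class_id is None:
            flag = "no"
        else:
            expected = set(class_table[c.class_id].domains)
            flag = "yes" if expected.intersection(domains) else "no"
        out.append(replace(c, pfam_domains=domains, pfam_consistent=flag))
    return out


def consistency_percentage(n_consistent: int, n_with_domain: int) -> float:
    """Percentage of domain-bearing sequences whose domain matches their
    class, to one decimal. Undefined (ValueError) when nothing has a domain."""
    if n_with_domain == 0:
        raise ValueError("no sequences with Pfam domains: percentage undefined")
    return round(100.0 * n_consistent / n_with_domain, 1)


def pfam_consistency_report(
    classifications: Iterable[Classification],
) -> tuple[int, int, float | None]:
    """(n_with_domain, n_consistent, pct) over classified sequences.

    ``pct`` is None (flagged undefined) when no classified sequence carries
    a domain annotation.
    """
    classified = [c for c in classifications if c.class_id is not None]
    with_domain = [c for c in classified if c.pfam_domains]
    consistent = [c for c in with_domain if c.pfam_consistent == "yes"]
    if not with_domain:
        return 0, 0, None
    return (len(with_domain), len(consistent),
            consistency_percentage(len(consistent), len(with_domain)))


def abundance_matrix(
    classifications: Iterable[Classification],
) -> pd.DataFrame:
    """Species x class count matrix over classified sequences."""
    rows = [(c.species or "unknown", c.class_id)
            for c in classifications if c.class_id is not None]
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows, columns=["species", "class_id"])
    return (df.value_counts().unstack(fill_value=0)
            .sort_index(axis=0).sort_index(axis=1))


def class_proportions(matrix: pd.DataFrame) -> pd.Series:
    """Per-class percentage of all classified sequences, to one decimal.

    Rounded entries can sum slightly off 100 (e.g. totals 984/918/187 of
    2089 give 47.1 + 43.9 + 9.0).
    """
    if matrix.empty:
        return pd.Series(dtype=float)
    totals = matrix.sum(axis=0)
    return (100.0 * totals / totals.sum()).round(1)
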