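"""Readers and writers for every external file format the pipeline touches.

All coordinates are 1-based inclusive internally. BED input (0-based,
half-open) is converted at this boundary and nowhere else.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SearchIO, SeqIO

from .topology import TMTopology

__all__ = [
    "ProteinRecord",
    "BlastHit",
    "HmmHit",
    "PfamAnnotation",
    "AfMetrics",
    "read_fasta",
    "write_fasta",
    "parse_blast_tab",
    "parse_tmhmm",
    "parse_hmm_table",
    "parse_pfam_table",
    "read_score_table",
    "write_score_table",
    "read_metrics_json",
    "read_intervals",
]

_PFAM_ACC_RE = re.compile(r"^PF\d{5}(\.\d+)?$")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier, species tag and amino-acid sequence."""

    id: str
    seq: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if any(c.isspace() for c in self.seq):
            raise ValueError(f"whitespace in sequence of record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class BlastHit:
    """One pairwise local-alignment hit in tabular (outfmt-6 style) form.

    Coordinates are 1-based inclusive and orientation-normalized so that
    start <= end on both query and subject. ``qlen``/``slen`` are required
    because the dual-coverage gate needs both full lengths.
    """

    qid: str
    sid: str
    evalue: float
    bitscore: float
    qstart: int
    qend: int
    sstart: int
    send: int
    qlen: int
    slen: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")
        if self.qlen < 1 or self.slen < 1:
            raise ValueError("qlen/slen must be >= 1")
        if not (1 <= self.qstart <= self.qend <= self.qlen):
            raise ValueError(
                f"query coordinates out of range for {self.qid}->{self.sid}"
            )
        if not (1 <= self.sstart <= self.send <= self.slen):
            raise ValueError(
                f"subject coordinates out of range for {self.qid}->{self.sid}"
            )

    @property
    def query_coverage(self) -> float:
        return (self.qend - self.qstart + 1) / self.qlen

    @property
    def subject_coverage(self) -> float:
        return (self.send - self.sstart + 1) / self.slen


@dataclass(frozen=True)
class HmmHit:
    """A per-sequence hmmsearch hit against one of the 14 class profiles."""

    target_id: str
    class_id: int
    evalue: float
    score: float

    def __post_init__(self) -> None:
        if not 1 <= self.class_id <= 14:
            raise ValueError(f"class_id must be in 1..14, got {self.class_id}")
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")


@dataclass(frozen=True)
class PfamAnnotation:
    """One Pfam domain annotation on one sequence."""

    seq_id: str
    domain_name: str
    pfam_acc: str
    evalue: float

    def __post_init__(self) -> None:
        if not _PFAM_ACC_RE.match(self.pfam_acc):
            raise ValueError(f"malformed Pfam accession {self.pfam_acc!r}")


@dataclass
class AfMetrics:
    """Structure-prediction confidence payload for one modeled complex.

    ``plddt`` is per-residue on the 0-100 scale, ``pae`` a square matrix in
    Angstroms over all residues, and ``chain_ranges`` an ordered mapping of
    chain id to 1-based inclusive (start, end) residue index ranges that
    tile 1..n_residues.
    """

    ptm: float
    iptm: float
    plddt: np.ndarray
    pae: np.ndarray
    chain_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.pae = np.asarray(self.pae, dtype=float)
        n = self.plddt.shape[0]
        if self.pae.shape != (n, n):
            raise ValueError(
                f"PAE matrix shape {self.pae.shape} does not match "
                f"{n} pLDDT residues"
            )
        if not (0.0 <= self.ptm <= 1.0 and 0.0 <= self.iptm <= 1.0):
            raise ValueError("ptm and iptm must be in [0, 1]")
        covered = []
        for cid, (start, end) in self.chain_ranges.items():
            if not (1 <= start <= end <= n):
                raise ValueError(f"chain {cid} range {start}-{end} out of 1..{n}")
            covered.extend(range(start, end + 1))
        if sorted(covered) != list(range(1, n + 1)):
            raise ValueError("chain ranges must be disjoint and tile 1..n")

    @property
    def n_residues(self) -> int:
        return int(self.plddt.shape[0])

    def chain_index(self, chain_id: str) -> np.ndarray:
        """0-based residue indices belonging to ``chain_id``."""
        start, end = self.chain_ranges[chain_id]
        return np.arange(start - 1, end)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, species: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA file into ``ProteinRecord`` objects.

    Sequences are uppercased; header order is preserved. Duplicate ids and
    empty sequences raise ``ValueError``.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA id {rec.id!r} in {path}")
        records.append(ProteinRecord(id=rec.id, seq=seq, species=species))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

#: standard -outfmt 6 column order
BLAST12_COLUMNS = (
    "qid", "sid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


def parse_blast_tab(
    path: str | Path,
    length_map: Mapping[str, int] | None = None,
) -> list[BlastHit]:
    """Parse BLAST tabular output (outfmt-6 style) into ``BlastHit`` objects.

    Two dialects are accepted: the standard 12 columns with two appended
    columns ``qlen slen`` (14 columns total), or the bare 12 columns plus a
    ``length_map`` from sequence id to full length covering every qid/sid.
    Subject coordinates on the minus strand (sstart > send) are swapped.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (12, 14):
                raise ValueError(
                    f"{path}:{lineno}: expected 12 or 14 tab-separated "
                    f"columns, got {len(parts)}"
                )
            row = dict(zip(BLAST12_COLUMNS, parts[:12]))
            if len(parts) == 14:
                qlen, slen = int(parts[12]), int(parts[13])
            else:
                if length_map is None:
                    raise ValueError(
                        f"{path}:{lineno}: 12-column BLAST line but no "
                        "length map supplied (qlen/slen required)"
                    )
                try:
                    qlen = int(length_map[row["qid"]])
                    slen = int(length_map[row["sid"]])
                except KeyError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: id {exc.args[0]!r} missing from "
                        "length map"
                    ) from None
            qstart, qend = int(row["qstart"]), int(row["qend"])
            sstart, send = int(row["sstart"]), int(row["send"])
            if qstart > qend:
                qstart, qend = qend, qstart
            if sstart > send:
                sstart, send = send, sstart
            hits.append(BlastHit(
                qid=row["qid"], sid=row["sid"],
                evalue=float(row["evalue"]), bitscore=float(row["bitscore"]),
                qstart=qstart, qend=qend, sstart=sstart, send=send,
                qlen=qlen, slen=slen,
            ))
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path: str | Path) -> None:
    """Write hits in the 14-column dialect (12 standard + qlen slen)."""
    with open(path, "w") as fh:
        for h in hits:
            aln = h.qend - h.qstart + 1
            fh.write("\t".join(map(str, (
                h.qid, h.sid, "0.0", aln, 0, 0,
                h.qstart, h.qend, h.sstart, h.send,
                f"{h.evalue:.3g}", h.bitscore, h.qlen, h.slen,
            ))) + "\n")


# ---------------------------------------------------------------------------
# TMHMM reports
# ---------------------------------------------------------------------------

_TMHMM_NHELIX_RE = re.compile(r"Number of predicted TMHs:\s*(\d+)")
_TMHMM_TOPO_STRING_RE = re.compile(r"^[io](\d+-\d+[io])*$")


def _segments_from_topology_string(topo: str, seq_len: int):
    """Expand a short-format topology string like ``o10-30i45-60o``."""
    sides = {"i": "inside", "o": "outside"}
    segments = []
    pos = 1
    side = sides[topo[0]]
    for m in re.finditer(r"(\d+)-(\d+)([io])", topo):
        start, end = int(m.group(1)), int(m.group(2))
        if start > pos:
            segments.append((side, pos, start - 1))
        segments.append(("TMhelix", start, end))
        side = sides[m.group(3)]
        pos = end + 1
    if pos <= seq_len:
        segments.append((side, pos, seq_len))
    return segments


def parse_tmhmm(path: str | Path) -> dict[str, TMTopology]:
    """Parse a TMHMM report into per-sequence topologies.

    Both output dialects are supported: the long format (one
    ``id TMHMM2.0 label start end`` line per segment, with ``#`` header
    lines) and the one-line short format (``PredHel=``/``Topology=``
    fields). When a ``Number of predicted TMHs`` header is present it is
    cross-checked against the parsed segment count.
    """
    per_seq_segments: dict[str, list[tuple[str, int, int]]] = {}
    declared_counts: dict[str, int] = {}
    declared_lengths: dict[str, int] = {}

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                m = _TMHMM_NHELIX_RE.search(body)
                if m:
                    declared_counts[body.split()[0]] = int(m.group(1))
                m = re.match(r"(\S+)\s+Length:\s*(\d+)", body)
                if m:
                    declared_lengths[m.group(1)] = int(m.group(2))
                continue
            parts = line.split()
            if "Topology=" in line and "len=" in line:
                # short one-line summary dialect
                fields = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
                seq_id = parts[0]
                seq_len = int(fields["len"])
                topo = fields["Topology"]
                segs = _segments_from_topology_string(topo, seq_len)
                per_seq_segments[seq_id] = segs
                declared_counts[seq_id] = int(fields.get("PredHel", len(
                    [s for s in segs if s[0] == "TMhelix"])))
                continue
            if len(parts) == 5 and parts[2] in ("inside", "outside", "TMhelix"):
                seq_id, _, label, start, end = parts
                per_seq_segments.setdefault(seq_id, []).append(
                    (label, int(start), int(end)))
                continue
            raise ValueError(f"unrecognized TMHMM line: {line!r}")

    out: dict[str, TMTopology] = {}
    for seq_id, segs in per_seq_segments.items():
        top = TMTopology.from_segments(segs)
        declared = declared_counts.get(seq_id)
        if declared is not None and declared != top.n_helices:
            raise ValueError(
                f"{seq_id}: declared {declared} TMHs but report contains "
                f"{top.n_helices} TMhelix segments"
            )
        declared_len = declared_lengths.get(seq_id)
        if declared_len is not None and declared_len != top.seq_len:
            raise ValueError(
                f"{seq_id}: declared length {declared_len} but segments "
                f"cover 1..{top.seq_len}"
            )
        out[seq_id] = top
    return out


def write_tmhmm(topologies: Mapping[str, TMTopology], path: str | Path) -> None:
    """Write topologies in the TMHMM long-format dialect."""
    with open(path, "w") as fh:
        for seq_id, top in topologies.items():
            fh.write(f"# {seq_id} Length: {top.seq_len}\n")
            fh.write(f"# {seq_id} Number of predicted TMHs:  {top.n_helices}\n")
            for label, start, end in top.segments:
                fh.write(f"{seq_id}\tTMHMM2.0\t{label}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# HMM / Pfam / score tables
# ---------------------------------------------------------------------------

_CLASS_IN_QUERY_RE = re.compile(r"(?:class[_\-.]?)(\d+)", re.IGNORECASE)


def parse_hmm_table(
    path: str | Path,
    query_class_map: Mapping[str, int] | None = None,
) -> list[HmmHit]:
    """Parse per-sequence HMM search hits into ``HmmHit`` objects.

    Accepts either hmmsearch ``--tblout`` output (class ids taken from the
    query profile name, via ``query_class_map`` or a ``class<k>`` pattern in
    the name) or a simple 4-column TSV ``target_id  class_id  evalue  score``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") or len(first.split()) > 6:
        return _parse_hmmsearch_tblout(path, query_class_map)
    hits: list[HmmHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 columns "
                    f"(target, class, evalue, score), got {len(parts)}"
                )
            hits.append(HmmHit(
                target_id=parts[0], class_id=int(parts[1]),
                evalue=float(parts[2]), score=float(parts[3]),
            ))
    return hits


def _parse_hmmsearch_tblout(path, query_class_map):
    hits = []
    for qresult in SearchIO.parse(str(path), "hmmer3-tab"):
        qname = qresult.id
        if query_class_map is not None:
            class_id = query_class_map[qname]
        else:
            m = _CLASS_IN_QUERY_RE.search(qname)
            if not m:
                raise ValueError(
                    f"cannot infer class id from query name {qname!r}; "
                    "pass query_class_map"
                )
            class_id = int(m.group(1))
        for hit in qresult.hits:
            hits.append(HmmHit(
                target_id=hit.id, class_id=class_id,
                evalue=float(hit.evalue), score=float(hit.bitscore),
            ))
    return hits


def parse_pfam_table(path: str | Path) -> list[PfamAnnotation]:
    """Parse a 4-column TSV ``seq_id  domain_name  pfam_acc  evalue``."""
    annots: list[PfamAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 columns, got {len(parts)}"
                )
            annots.append(PfamAnnotation(
                seq_id=parts[0], domain_name=parts[1],
                pfam_acc=parts[2], evalue=float(parts[3]),
            ))
    return annots


def write_pfam_table(annots: Iterable[PfamAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in annots:
            fh.write(f"{a.seq_id}\t{a.domain_name}\t{a.pfam_acc}\t{a.evalue:g}\n")


def read_score_table(path: str | Path) -> dict[str, float]:
    """Read a 2-column TSV ``seq_id  score`` with scores in [0, 1]."""
    scores: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            seq_id, raw = parts
            score = float(raw)
            if not 0.0 <= score <= 1.0:
                raise ValueError(
                    f"{path}:{lineno}: score {score} for {seq_id!r} "
                    "outside [0, 1]"
                )
            scores[seq_id] = score
    return scores


def write_score_table(scores: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, score in scores.items():
            fh.write(f"{seq_id}\t{score:.6f}\n")


# ---------------------------------------------------------------------------
# Structure-prediction metrics payload (canonical JSON schema)
# ---------------------------------------------------------------------------

def read_metrics_json(path: str | Path) -> AfMetrics:
    """Read the canonical metrics payload.

    Schema::

        {
          "ptm": 0.8, "iptm": 0.7,
          "plddt": [..per-residue, 0-100..],
          "pae":   [[..n x n, Angstrom..]],
          "chain_ranges": {"A": [1, 120], "B": [121, 250]}
        }

    ``chain_ranges`` may also be a list of ``[chain_id, start, end]``
    triples; insertion order defines chain order either way.
    """
    with open(path) as fh:
        payload = json.load(fh)
    raw_ranges = payload["chain_ranges"]
    if isinstance(raw_ranges, Mapping):
        ranges = {str(k): (int(v[0]), int(v[1])) for k, v in raw_ranges.items()}
    else:
        ranges = {str(c): (int(s), int(e)) for c, s, e in raw_ranges}
    return AfMetrics(
        ptm=float(payload["ptm"]),
        iptm=float(payload["iptm"]),
        plddt=np.asarray(payload["plddt"], dtype=float),
        pae=np.asarray(payload["pae"], dtype=float),
        chain_ranges=ranges,
    )


def write_metrics_json(metrics: AfMetrics, path: str | Path) -> None:
    payload = {
        "ptm": metrics.ptm,
        "iptm": metrics.iptm,
        "plddt": metrics.plddt.tolist(),
        "pae": metrics.pae.tolist(),
        "chain_ranges": {c: list(r) for c, r in metrics.chain_ranges.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


# ---------------------------------------------------------------------------
# Genomic intervals (BED / GFF3)
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read genomic intervals from BED or GFF3 into a DataFrame.

    Returns columns ``scaffold, start, end, feature_id`` with 1-based
    inclusive coordinates (BED's 0-based half-open convention is converted
    here). ``fmt`` defaults to the file suffix.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2, 3],
                         names=["scaffold", "start", "end", "feature_id"],
                         dtype={"scaffold": str, "feature_id": str})
        df["start"] = df["start"].astype(int) + 1  # 0-based half-open -> 1-based
        df["end"] = df["end"].astype(int)
    elif fmt == "gff3":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["scaffold", "source", "type", "start", "end",
                                "score", "strand", "phase", "attributes"],
                         dtype={"scaffold": str})
        ids = df["attributes"].str.extract(r"ID=([^;]+)")[0]
        df = pd.DataFrame({
            "scaffold": df["scaffold"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "feature_id": ids.fillna(
                pd.Series((f"feature_{i}" for i in range(len(df))))),
        })
    else:
        raise ValueError(f"unknown interval format {fmt!r}")
    bad = df[df["start"] > df["end"]]
    if len(bad):
        raise ValueError(f"{path}: start > end for {bad.iloc[0]['feature_id']}")
    return df
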