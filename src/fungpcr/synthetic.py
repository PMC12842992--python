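"""Seeded generators for every fixture class the pipeline consumes:
membrane-protein sequences with known topology, decoys, CNN training
benchmarks, evidence tables, and structure/metrics payloads with tunable
interface quality.

Design notes. Helix segments draw from a strongly hydrophobic,
low-variance alphabet (I/V/L) and loops from a moderately hydrophilic one
(P/Y/S), so the Kyte-Doolittle fallback predictor recovers the designed
helices with a wide margin on both the run-length and the inter-helix-dip
side; segment composition makes no attempt at biological realism. Every
generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from biotite.structure import AtomArray

from .io_formats import AfMetrics, BlastHit, HmmHit, PfamAnnotation, ProteinRecord
from .topology import TMTopology

__all__ = [
    "GeneratorConfig",
    "make_gpcr_like",
    "make_decoys",
    "make_cnn_benchmark",
    "make_af_fixture",
    "make_screen_bundle",
]

HELIX_ALPHABET = np.array(list("IVL"))
HELIX_WEIGHTS = np.array([0.60, 0.25, 0.15])
LOOP_ALPHABET = np.array(list("PYS"))
LOOP_WEIGHTS = np.array([0.60, 0.30, 0.10])


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the sequence and structure generators.

    ``decoy_kind`` is one of ``wrong_count`` (with ``wrong_count_k``
    helices), ``inverted`` (intracellular N-terminus) or ``soluble`` (no
    helices); ``interface_q`` in [0, 1] sets the interface quality of
    structure-metrics fixtures.
    """

    seed: int = 0
    n_helices: int = 7
    helix_len: tuple[int, int] = (18, 25)
    loop_len: tuple[int, int] = (10, 40)
    decoy_kind: str = "soluble"
    wrong_count_k: int = 5
    interface_q: float = 1.0

    def __post_init__(self) -> None:
        if self.helix_len[0] < 1 or self.loop_len[0] < 1:
            raise ValueError("length ranges must be positive")
        if not 0.0 <= self.interface_q <= 1.0:
            raise ValueError("interface_q must be in [0, 1]")


def _draw(rng, alphabet, weights, length: int) -> str:
    return "".join(rng.choice(alphabet, size=length, p=weights))


def _membrane_protein(
    rng: np.random.Generator,
    n_helices: int,
    helix_len: tuple[int, int],
    loop_len: tuple[int, int],
    n_term_side: str,
) -> tuple[str, TMTopology]:
    """One sequence with ``n_helices`` hydrophobic segments and its true
    topology; sides alternate starting from ``n_term_side``."""
    other = {"inside": "outside", "outside": "inside"}
    side = n_term_side
    parts: list[str] = []
    segments: list[tuple[str, int, int]] = []
    pos = 1
    for h in range(n_helices):
        llen = int(rng.integers(loop_len[0], loop_len[1] + 1))
        parts.append(_draw(rng, LOOP_ALPHABET, LOOP_WEIGHTS, llen))
        segments.append((side, pos, pos + llen - 1))
        pos += llen
        hlen = int(rng.integers(helix_len[0], helix_len[1] + 1))
        parts.append(_draw(rng, HELIX_ALPHABET, HELIX_WEIGHTS, hlen))
        segments.append(("TMhelix", pos, pos + hlen - 1))
        pos += hlen
        side = other[side]
    llen = int(rng.integers(loop_len[0], loop_len[1] + 1))
    parts.append(_draw(rng, LOOP_ALPHABET, LOOP_WEIGHTS, llen))
    segments.append((side, pos, pos + llen - 1))
    pos += llen
    seq = "".join(parts)
    return seq, TMTopology.from_segments(segments, seq_len=len(seq))


def make_gpcr_like(
    n: int,
    config: GeneratorConfig = GeneratorConfig(),
    prefix: str = "gpcr",
    species: str = "synthsp",
) -> tuple[list[ProteinRecord], dict[str, TMTopology]]:
    """``n`` receptor-like sequences with ground-truth topology.

    Each has exactly ``config.n_helices`` hydrophobic segments separated by
    hydrophilic loops, an extracellular N-terminus, and (for odd helix
    counts) an intracellular C-terminus. Same seed, same output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed)
    records, topologies = [], {}
    for i in range(n):
        seq, top = _membrane_protein(
            rng, config.n_helices, config.helix_len, config.loop_len,
            n_term_side="outside")
        rec = ProteinRecord(id=f"{prefix}_{i:05d}", seq=seq, species=species)
        records.append(rec)
        topologies[rec.id] = top
    return records, topologies


def make_decoys(
    n: int,
    config: GeneratorConfig,
    prefix: str = "decoy",
    species: str = "synthsp",
) -> tuple[list[ProteinRecord], dict[str, TMTopology]]:
    """Decoy sequences of the configured kind with ground-truth topology.

    ``wrong_count``: ``wrong_count_k`` helices, normal orientation start;
    ``inverted``: seven helices but intracellular N-terminus;
    ``soluble``: all-loop sequences (length drawn to match a typical
    7-helix protein so composition, not length, distinguishes them).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed)
    records, topologies = [], {}
    for i in range(n):
        kind = config.decoy_kind
        if kind == "wrong_count":
            seq, top = _membrane_protein(
                rng, config.wrong_count_k, config.helix_len, config.loop_len,
                n_term_side="outside")
        elif kind == "inverted":
            seq, top = _membrane_protein(
                rng, config.n_helices, config.helix_len, config.loop_len,
                n_term_side="inside")
        elif kind == "soluble":
            mean_helix = sum(config.helix_len) / 2
            mean_loop = sum(config.loop_len) / 2
            typical = int(config.n_helices * mean_helix
                          + (config.n_helices + 1) * mean_loop)
            length = int(rng.integers(int(typical * 0.8), int(typical * 1.2)))
            seq = _draw(rng, LOOP_ALPHABET, LOOP_WEIGHTS, length)
            top = TMTopology.from_segments([("outside", 1, length)], length)
        else:
            raise ValueError(f"unknown decoy kind {kind!r}")
        rec = ProteinRecord(id=f"{prefix}_{kind}_{i:05d}", seq=seq,
                            species=species)
        records.append(rec)
        topologies[rec.id] = top
    return records, topologies


def make_cnn_benchmark(
    n_pos: int, n_neg: int, seed: int,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Separable training benchmark for the sequence classifier.

    Positives are seven-helix receptor-like sequences; negatives an even
    mixture of soluble, three-helix and twelve-helix decoys. Soluble decoy
    lengths are drawn to overlap the positive length distribution.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both classes need at least one sequence")
    root = np.random.default_rng(seed)
    s_pos, s_sol, s_3tm, s_12tm = root.integers(0, 2**31 - 1, size=4)
    positives, _ = make_gpcr_like(
        n_pos, GeneratorConfig(seed=int(s_pos)), prefix="pos")
    thirds = [n_neg // 3, n_neg // 3, n_neg - 2 * (n_neg // 3)]
    negatives: list[ProteinRecord] = []
    specs = [
        (thirds[0], GeneratorConfig(seed=int(s_sol), decoy_kind="soluble"),
         "neg_sol"),
        (thirds[1], GeneratorConfig(seed=int(s_3tm), decoy_kind="wrong_count",
                                    wrong_count_k=3), "neg_3tm"),
        (thirds[2], GeneratorConfig(seed=int(s_12tm), decoy_kind="wrong_count",
                                    wrong_count_k=12), "neg_12tm"),
    ]
    for count, cfg, prefix in specs:
        if count:
            recs, _ = make_decoys(count, cfg, prefix=prefix)
            negatives.extend(recs)
    return positives, negatives


# ---------------------------------------------------------------------------
# structure + metrics fixtures
# ---------------------------------------------------------------------------

_CA_SPACING = 3.8  # Angstroms between consecutive CA atoms
_CONTACT_OFFSET = 5.0  # inter-chain distance inside the designed patch
_FAR = 60.0


def _ca_chain(chain_id: str, coords: np.ndarray) -> AtomArray:
    n = len(coords)
    atoms = AtomArray(n)
    atoms.coord = coords.astype(np.float32)
    atoms.chain_id = np.full(n, chain_id)
    atoms.res_id = np.arange(1, n + 1)
    atoms.res_name = np.full(n, "ALA")
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    return atoms


def make_af_fixture(
    n_chains: int,
    residues_per_chain: int = 60,
    q: float = 1.0,
    seed: int = 0,
    contact_patch: int = 10,
    detached: bool = False,
) -> tuple[AtomArray, AfMetrics]:
    """A synthetic complex (CA trace) plus a matching metrics payload.

    Chains A..D are straight CA traces; each non-A chain touches chain A
    over a ``contact_patch``-residue designed patch (unless ``detached``,
    which separates the chains entirely). Quality ``q`` sets interface
    PAE to ``31*(1-q) + 1`` (off-interface 30), pLDDT to ``40 + 60*q``
    everywhere, pTM to ``0.2 + 0.6*q`` and ipTM to ``0.1 + 0.8*q``.
    """
    if n_chains not in (2, 4):
        raise ValueError("n_chains must be 2 (pair) or 4 (heterotrimer)")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    r = residues_per_chain
    if n_chains == 4 and r < 50:
        raise ValueError("heterotrimer fixture needs >= 50 residues/chain")
    idx = np.arange(r)

    def straight(x0, y0, veer_from, veer_sign):
        x = x0 + idx * _CA_SPACING
        y = np.full(r, float(y0))
        past = idx >= veer_from
        y[past] += veer_sign * 12.0 * (idx[past] - veer_from + 1)
        return np.column_stack([x, y, np.zeros(r)])

    chain_ids = ["A", "B", "C", "D"][:n_chains]
    coords = {"A": np.column_stack([idx * _CA_SPACING, np.zeros(r),
                                    np.zeros(r)])}
    # anchor x-position (in residues of chain A) of each partner's patch
    anchors = {"B": 0, "C": 20, "D": 40}
    for c in chain_ids[1:]:
        if detached:
            coords[c] = np.column_stack([
                idx * _CA_SPACING, np.full(r, _FAR * (ord(c) - 65)),
                np.zeros(r)])
        else:
            sign = -1.0 if c == "C" else 1.0
            coords[c] = straight(anchors[c] * _CA_SPACING,
                                 sign * _CONTACT_OFFSET,
                                 contact_patch, sign)
    structure = _ca_chain(chain_ids[0], coords["A"])
    for c in chain_ids[1:]:
        structure += _ca_chain(c, coords[c])

    n_total = n_chains * r
    plddt = np.full(n_total, 40.0 + 60.0 * q)
    pae = np.full((n_total, n_total), 30.0)
    np.fill_diagonal(pae, 0.5)
    interface_pae = 31.0 * (1.0 - q) + 1.0

    ranges = {c: (i * r + 1, (i + 1) * r) for i, c in enumerate(chain_ids)}
    if not detached:
        # mark the designed patch pairs (and a 1-residue fringe) low-PAE
        for ci, c in enumerate(chain_ids[1:], start=1):
            a0 = anchors[c]
            for i in range(a0, min(a0 + contact_patch + 2, r)):
                for j in range(0, contact_patch + 2):
                    gi = i           # chain A global index
                    gj = ci * r + j  # partner global index
                    pae[gi, gj] = pae[gj, gi] = interface_pae
    metrics = AfMetrics(
        ptm=0.2 + 0.6 * q,
        iptm=0.1 + 0.8 * q,
        plddt=plddt,
        pae=pae,
        chain_ranges=ranges,
    )
    return structure, metrics


# ---------------------------------------------------------------------------
# end-to-end screen bundle
# ---------------------------------------------------------------------------

@dataclass
class ScreenBundle:
    """A mixed proteome with planted class labels and evidence tables."""

    records: list[ProteinRecord]
    topologies: dict[str, TMTopology]
    truth: dict[str, int | None]            # planted class (None = decoy)
    hmm_hits: list[HmmHit]
    pfam_annotations: list[PfamAnnotation]
    blast_hits: list[BlastHit]


def make_screen_bundle(
    seed: int = 0,
    n_per_class: int = 3,
    classes: Sequence[int] = tuple(range(1, 15)),
    n_decoys_per_kind: int = 5,
) -> ScreenBundle:
    """Proteome + evidence emulating the identification cascade's inputs.

    For each requested fungal class, ``n_per_class`` seven-helix sequences
    are planted with a strong HMM hit to their class (E-value 1e-12), a
    weak off-class hit, the class-diagnostic Pfam domain, and a satisfying
    self-consistent BLAST hit. Decoys (wrong helix count, inverted
    orientation, soluble) get equally strong evidence so only the
    topology gates can reject them.
    """
    from .classify import CLASS_TABLE  # local import to avoid a cycle

    root = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    topologies: dict[str, TMTopology] = {}
    truth: dict[str, int | None] = {}
    hmm_hits: list[HmmHit] = []
    pfam: list[PfamAnnotation] = []
    blast: list[BlastHit] = []

    for class_id in classes:
        cfg = GeneratorConfig(seed=int(root.integers(0, 2**31 - 1)))
        recs, tops = make_gpcr_like(n_per_class, cfg,
                                    prefix=f"c{class_id:02d}")
        cls = CLASS_TABLE[class_id]
        for rec in recs:
            records.append(rec)
            topologies[rec.id] = tops[rec.id]
            truth[rec.id] = class_id
            hmm_hits.append(HmmHit(rec.id, class_id, 1e-12, 90.0))
            off = 1 + (class_id % 14)
            hmm_hits.append(HmmHit(rec.id, off, 1e-6, 20.0))
            pfam.append(PfamAnnotation(rec.id, cls.domains[0],
                                       cls.accessions[0], 1e-10))
            L = len(rec.seq)
            span = int(L * 0.9)
            blast.append(BlastHit(
                qid=f"query_c{class_id:02d}", sid=rec.id, evalue=1e-30,
                bitscore=200.0, qstart=1, qend=span, sstart=1, send=span,
                qlen=span, slen=L))

    decoy_kinds = [("wrong_count", 5), ("wrong_count", 8), ("inverted", 7),
                   ("soluble", 0)]
    for kind, k in decoy_kinds:
        cfg = GeneratorConfig(seed=int(root.integers(0, 2**31 - 1)),
                              decoy_kind=kind, wrong_count_k=k)
        recs, tops = make_decoys(n_decoys_per_kind, cfg,
                                 prefix=f"decoy{k}")
        for rec in recs:
            records.append(rec)
            topologies[rec.id] = tops[rec.id]
            truth[rec.id] = None
            planted = int(root.integers(1, 15))
            hmm_hits.append(HmmHit(rec.id, planted, 1e-12, 90.0))
    return ScreenBundle(records=records, topologies=topologies, truth=truth,
                        hmm_hits=hmm_hits, pfam_annotations=pfam,
                        blast_hits=blast)
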