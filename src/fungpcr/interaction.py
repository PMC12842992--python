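"""Structure-prediction-based interaction triage for receptor/G-protein
complexes.

Three quantities drive the triage of a modeled complex:

* ranking confidence ``0.8*ipTM + 0.2*pTM`` — overall model ranking, with
  tiers at >0.5 (good), >0.75 (very high) and >0.8 (top);
* mean pLDDT over all residues, with >80 flagged high-confidence;
* per-chain pDockQ2, a sigmoid-form interface-quality score combining
  interface pLDDT with a PAE-derived term, with min-over-chains > 0.23
  flagging a high-confidence interaction. For a receptor plus heterotrimeric
  G protein (four chains), every chain must clear 0.23.

pDockQ2 for chain ``c``::

    x_c = <pLDDT_i>_{i in I_c} * < 1 / (1 + (PAE_ij / d0)^2) >_{(i,j) in P_c}
    pDockQ2_c = L / (1 + exp(-k (x_c - x0))) + b

where ``P_c`` are inter-chain residue contacts involving chain ``c``
(heavy atoms within 8 A), ``I_c`` the chain-``c`` residues among them, and
(L, x0, k, b, d0) = (1.31, 84.733, 0.075, 0.005, 10.0) are the published
fitted constants, transcribed verbatim and never re-fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile

from .io_formats import AfMetrics

__all__ = [
    "PDOCKQ2_CONSTANTS",
    "InteractionAssessment",
    "ranking_confidence",
    "interface_residues",
    "interface_contacts",
    "pdockq2_chain",
    "assess_pair",
    "assess_heterotrimer",
    "load_structure",
]

#: Published sigmoid constants of the per-chain pDockQ2 score (versioned;
#: not re-fit): L / (1 + exp(-k (x - x0))) + b, with d0 the PAE
#: normalization distance in Angstroms.
PDOCKQ2_CONSTANTS = {
    "L": 1.31,
    "x0": 84.733,
    "k": 0.075,
    "b": 0.005,
    "d0": 10.0,
}

#: Heavy-atom distance defining an inter-chain residue contact (Angstroms).
INTERFACE_CUTOFF = 8.0

#: min pDockQ2 above which an interface is called high-confidence.
PDOCKQ2_THRESHOLD = 0.23

#: mean pLDDT above which a model is flagged high-confidence.
PLDDT_HIGH = 80.0


@dataclass(frozen=True)
class InteractionAssessment:
    """Triage result for one modeled complex."""

    confidence: float
    mean_plddt: float
    pdockq2: dict[str, float]
    min_pdockq2: float
    tier: str                         # none | good | very_high | top
    high_confidence_interface: bool   # min pDockQ2 > 0.23
    plddt_high: bool                  # mean pLDDT > 80
    empty_interface_chains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tier != _tier(self.confidence):
            raise ValueError("tier inconsistent with ranking confidence")
        if self.high_confidence_interface != (
                self.min_pdockq2 > PDOCKQ2_THRESHOLD):
            raise ValueError("interface flag inconsistent with min pDockQ2")


def _tier(confidence: float) -> str:
    if confidence > 0.8:
        return "top"
    if confidence > 0.75:
        return "very_high"
    if confidence > 0.5:
        return "good"
    return "none"


def ranking_confidence(ptm: float, iptm: float) -> float:
    """Model ranking confidence ``0.8*ipTM + 0.2*pTM``."""
    if not (0.0 <= ptm <= 1.0 and 0.0 <= iptm <= 1.0):
        raise ValueError("ptm and iptm must be in [0, 1]")
    return 0.8 * iptm + 0.2 * ptm


def load_structure(pdb: str | Path | AtomArray) -> AtomArray:
    if isinstance(pdb, AtomArray):
        return pdb
    structure = PDBFile.read(str(pdb)).get_structure(model=1)
    return structure


def _chain_residue_atoms(structure: AtomArray, chain_id: str):
    """Residue ids (in chain order) and per-residue coordinate blocks."""
    mask = structure.chain_id == chain_id
    if not mask.any():
        raise ValueError(f"chain {chain_id!r} not present in structure")
    sub = structure[mask & (structure.element != "H")]
    res_ids = np.unique(sub.res_id)
    coords = [sub.coord[sub.res_id == r] for r in res_ids]
    return res_ids, coords


def interface_contacts(
    structure: AtomArray | str | Path,
    chain_a: str,
    chain_b: str,
    cutoff: float = INTERFACE_CUTOFF,
) -> list[tuple[int, int]]:
    """Inter-chain residue contact pairs ``(res_a, res_b)``.

    Residues are in contact when any heavy atom of one is within ``cutoff``
    of any heavy atom of the other; ``res_a``/``res_b`` index residues
    0-based in chain order.
    """
    structure = load_structure(structure)
    ids_a, coords_a = _chain_residue_atoms(structure, chain_a)
    ids_b, coords_b = _chain_residue_atoms(structure, chain_b)
    contacts = []
    for i, ca in enumerate(coords_a):
        for j, cb in enumerate(coords_b):
            d2 = ((ca[:, None, :] - cb[None, :, :]) ** 2).sum(-1)
            if (d2 <= cutoff * cutoff).any():
                contacts.append((i, j))
    return contacts


def interface_residues(
    structure: AtomArray | str | Path,
    chain_a: str,
    chain_b: str,
    cutoff: float = INTERFACE_CUTOFF,
) -> tuple[set[int], set[int]]:
    """Per-chain interfacial residue sets (0-based chain-order indices)."""
    contacts = interface_contacts(structure, chain_a, chain_b, cutoff)
    return {i for i, _ in contacts}, {j for _, j in contacts}


def pdockq2_chain(
    metrics: AfMetrics,
    structure: AtomArray | str | Path,
    chain_id: str,
    cutoff: float = INTERFACE_CUTOFF,
) -> tuple[float, bool]:
    """Per-chain pDockQ2 score.

    Returns ``(score, has_interface)``; a chain with no inter-chain contact
    scores 0 with ``has_interface=False`` (no interaction surface).
    """
    structure = load_structure(structure)
    chains = list(metrics.chain_ranges)
    if chain_id not in chains:
        raise ValueError(f"chain {chain_id!r} not in metrics payload")

    offset = {c: metrics.chain_ranges[c][0] - 1 for c in chains}
    pairs: list[tuple[int, int]] = []  # global residue indices (0-based)
    for other in chains:
        if other == chain_id:
            continue
        for i, j in interface_contacts(structure, chain_id, other, cutoff):
            pairs.append((offset[chain_id] + i, offset[other] + j))
    if not pairs:
        return 0.0, False

    own = sorted({i for i, _ in pairs})
    mean_if_plddt = float(metrics.plddt[own].mean())
    d0 = PDOCKQ2_CONSTANTS["d0"]
    pae_terms = [1.0 / (1.0 + (metrics.pae[i, j] / d0) ** 2) for i, j in pairs]
    x = mean_if_plddt * float(np.mean(pae_terms))
    c = PDOCKQ2_CONSTANTS
    score = c["L"] / (1.0 + np.exp(-c["k"] * (x - c["x0"]))) + c["b"]
    return float(score), True


def _assess(metrics: AfMetrics, structure, expected_chains: int,
            cutoff: float) -> InteractionAssessment:
    structure = load_structure(structure)
    chains = list(metrics.chain_ranges)
    if len(chains) != expected_chains:
        raise ValueError(
            f"expected {expected_chains} chains, metrics payload has "
            f"{len(chains)}")
    pdb_chains = set(np.unique(structure.chain_id))
    missing = [c for c in chains if c not in pdb_chains]
    if missing:
        raise ValueError(f"chains {missing} absent from coordinates")

    scores: dict[str, float] = {}
    empty: list[str] = []
    for c in chains:
        score, has_if = pdockq2_chain(metrics, structure, c, cutoff)
        scores[c] = score
        if not has_if:
            empty.append(c)
    min_score = min(scores.values())
    conf = ranking_confidence(metrics.ptm, metrics.iptm)
    mean_plddt = float(metrics.plddt.mean())
    return InteractionAssessment(
        confidence=conf,
        mean_plddt=mean_plddt,
        pdockq2=scores,
        min_pdockq2=min_score,
        tier=_tier(conf),
        high_confidence_interface=min_score > PDOCKQ2_THRESHOLD,
        plddt_high=mean_plddt > PLDDT_HIGH,
        empty_interface_chains=tuple(empty),
    )


def assess_pair(metrics: AfMetrics, structure,
                cutoff: float = INTERFACE_CUTOFF) -> InteractionAssessment:
    """Triage a receptor/G-alpha pair (two chains)."""
    return _assess(metrics, structure, 2, cutoff)


def assess_heterotrimer(metrics: AfMetrics, structure,
                        cutoff: float = INTERFACE_CUTOFF
                        ) -> InteractionAssessment:
    """Triage a receptor plus G-protein heterotrimer (four chains); the
    high-confidence call requires all four chains above 0.23."""
    return _assess(metrics, structure, 4, cutoff)


def best_of_models(assessments) -> InteractionAssessment:
    """Across repeated models of the same pair, keep the assessment with
    the highest ranking confidence."""
    assessments = list(assessments)
    if not assessments:
        raise ValueError("no assessments given")
    return max(assessments, key=lambda a: a.confidence)
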