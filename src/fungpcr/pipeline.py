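"""The three end-to-end workflows, wired from the library modules:
the known-class screen, novel-candidate consensus, and structure-based
interaction triage. Each writes a TSV stamped with the tool version and a
hash of the configuration so identical configs give byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import classify, consensus, interaction, io_formats

__all__ = ["ScreenConfig", "run_screen", "run_novel", "run_afscore"]


def _require(path, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} file not found: {p}")
    return p


def _config_hash(params: dict) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, out, params: dict) -> None:
    with open(out, "w") as fh:
        fh.write(f"# fungpcr {__version__}\n")
        fh.write(f"# config_hash {_config_hash(params)}\n")
        for key, value in sorted(params.items()):
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


@dataclass
class ScreenConfig:
    """Inputs and thresholds of the known-class screen.

    Defaults are the published operating point: E-value gates at 1e-5,
    dual BLAST coverage > 0.75, per-class helix-count rules, canonical
    orientation required.
    """

    fasta: str
    hmm: str
    tmhmm: str
    pfam: str | None = None
    blast: str | None = None
    emax: float = 1e-5
    min_cov: float = 0.75
    species: str = ""


def run_screen(config: ScreenConfig, out: str | Path) -> pd.DataFrame:
    """Run the identification cascade and write a classification TSV."""
    records = io_formats.read_fasta(_require(config.fasta, "FASTA"),
                                    species=config.species)
    topologies = io_formats.parse_tmhmm(_require(config.tmhmm, "TMHMM"))
    hmm_hits = classify.hmm_gate(
        io_formats.parse_hmm_table(_require(config.hmm, "HMM table")),
        emax=config.emax)

    blast_survivors: set[str] | None = None
    if config.blast is not None:
        hits = io_formats.parse_blast_tab(
            _require(config.blast, "BLAST"),
            length_map={r.id: len(r.seq) for r in records})
        blast_survivors = {
            h.sid for h in classify.blast_gate(
                hits, emax=config.emax, min_cov=config.min_cov)}

    results = []
    for rec in records:
        top = topologies.get(rec.id)
        if top is None:
            continue
        c = classify.assign_class(rec.id, hmm_hits, top,
                                  species=config.species or rec.species)
        if blast_survivors is not None:
            c.blast_pass = rec.id in blast_survivors
        results.append(c)

    if config.pfam is not None:
        annots = io_formats.parse_pfam_table(_require(config.pfam, "Pfam"))
        results = classify.annotate_pfam_consistency(results, annots)

    df = pd.DataFrame([{
        "seq_id": c.seq_id, "class_id": c.class_id, "species": c.species,
        "blast_pass": c.blast_pass, "hmm_pass": c.hmm_pass,
        "tmh_pass": c.tmh_pass, "topology_pass": c.topology_pass,
        "pfam_domains": ";".join(c.pfam_domains),
        "pfam_consistent": c.pfam_consistent,
        "best_evalue": c.best_evalue,
    } for c in results])
    params = {k: v for k, v in asdict(config).items()}
    _write_tsv(df, out, params)
    return df


def run_novel(proteinfer: str, deepfri: str, cnn_scores: str,
              out: str | Path,
              thresholds=consensus.DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Combine three model score tables into a consensus TSV."""
    tables = [io_formats.read_score_table(_require(p, name))
              for p, name in ((proteinfer, "ProteInfer scores"),
                              (deepfri, "DeepFRI scores"),
                              (cnn_scores, "CNN scores"))]
    df = consensus.consensus_table(*tables, thresholds=thresholds)
    params = {"proteinfer": proteinfer, "deepfri": deepfri,
              "cnn": cnn_scores, "thresholds": thresholds}
    _write_tsv(df, out, params)
    return df


def run_afscore(pdb: str, metrics: str, mode: str,
                out: str | Path) -> pd.DataFrame:
    """Assess one modeled complex (pair or heterotrimer) into a TSV."""
    m = io_formats.read_metrics_json(_require(metrics, "metrics JSON"))
    structure = interaction.load_structure(_require(pdb, "PDB"))
    if mode == "pair":
        a = interaction.assess_pair(m, structure)
    elif mode == "trimer":
        a = interaction.assess_heterotrimer(m, structure)
    else:
        raise ValueError(f"mode must be 'pair' or 'trimer', got {mode!r}")
    row = {
        "confidence": round(a.confidence, 4),
        "mean_plddt": round(a.mean_plddt, 2),
        "min_pdockq2": round(a.min_pdockq2, 4),
        "tier": a.tier,
        "high_confidence_interface": a.high_confidence_interface,
        "plddt_high": a.plddt_high,
    }
    for chain, score in a.pdockq2.items():
        row[f"pdockq2_{chain}"] = round(score, 4)
    df = pd.DataFrame([row])
    _write_tsv(df, out, {"pdb": pdb, "metrics": metrics, "mode": mode})
    return df
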