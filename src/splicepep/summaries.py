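"""Batch database construction and proteome-wide summaries.

Two peptide databases reflect the usual experimental regimes: full digestion
(0 missed cleavages) and up to two missed cleavages, each filtered to the
MS-detectable 6-60 residue window by default.  The summaries cover
per-enzyme sequence-coverage distributions, the missed-cleavage count
distribution, and per-event-type detectability tallies.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .digestion import (
    STANDARD_ENZYMES,
    DigestParams,
    digest_transcriptome,
    missed_cleavage_distribution,
    peptides_to_table,
)
from .events import derive_events, event_detectability, match_event_to_transcripts
from .io import read_annotation, read_genome
from .mapping import map_peptide, mapped_peptides_to_bed12
from .model import GeneModel, Genome, transcript_protein
from .specificity import sequence_coverage

__all__ = ["RunConfig", "ProteomeSummary", "build_database", "summarize_proteome"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome_path: str
    gtf_path: str
    out_dir: str
    enzymes: list[str] = field(default_factory=lambda: list(STANDARD_ENZYMES))
    missed_cleavage_levels: tuple[int, ...] = (0, 2)
    min_len: int = 6
    max_len: int = 60
    seed: int = 1

    def load(self) -> tuple[Genome, list[GeneModel]]:
        return read_genome(self.genome_path), read_annotation(self.gtf_path)


@dataclass
class ProteomeSummary:
    coverage: pd.DataFrame  # columns: enzyme, transcript_id, coverage
    coverage_stats: pd.DataFrame  # columns: enzyme, mean, median
    missed_cleavage_counts: dict[int, int]
    detectability: pd.DataFrame  # columns: event_type, verdict, count


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_database(cfg: RunConfig) -> dict:
    """Write per-enzyme peptide tables + BED12 tracks for each mc level.

    Returns the manifest (also written as JSON) recording parameters and
    input checksums.  On failure, partial outputs are removed.
    """
    genome, genes = cfg.load()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest = {
        "inputs": {
            "genome": {"path": str(cfg.genome_path), "sha256": _sha256(cfg.genome_path)},
            "gtf": {"path": str(cfg.gtf_path), "sha256": _sha256(cfg.gtf_path)},
        },
        "params": {
            "enzymes": list(cfg.enzymes),
            "missed_cleavage_levels": list(cfg.missed_cleavage_levels),
            "min_len": cfg.min_len,
            "max_len": cfg.max_len,
        },
        "databases": [],
    }
    try:
        for enzyme in cfg.enzymes:
            for mc in cfg.missed_cleavage_levels:
                params = DigestParams(
                    enzyme=enzyme,
                    max_missed_cleavages=mc,
                    min_len=cfg.min_len,
                    max_len=cfg.max_len,
                )
                _, per_t = digest_transcriptome(genes, genome, params)
                peptides = [p for peps in per_t.values() for p in peps]
                tsv = out / f"peptides.{enzyme}.mc{mc}.tsv"
                peptides_to_table(peptides).to_csv(tsv, sep="\t", index=False)
                written.append(tsv)
                by_tid = {
                    t.transcript_id: t for g in genes for t in g.transcripts
                }
                mps = [map_peptide(by_tid[p.transcript_id], p) for p in peptides]
                bed = out / f"peptides.{enzyme}.mc{mc}.bed"
                bed.write_text("\n".join(mapped_peptides_to_bed12(mps)) + "\n")
                written.append(bed)
                manifest["databases"].append(
                    {
                        "enzyme": enzyme,
                        "max_missed_cleavages": mc,
                        "peptide_table": tsv.name,
                        "bed12": bed.name,
                        "n_peptides": len(peptides),
                    }
                )
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return manifest


def summarize_proteome(
    cfg: RunConfig,
    genome: Genome | None = None,
    genes: list[GeneModel] | None = None,
    write_outputs: bool = True,
) -> ProteomeSummary:
    """Coverage, missed-cleavage and detectability summaries for an annotation.

    Coverage uses full digestion (mc=0) with the length filter; the
    missed-cleavage distribution uses the trypsin mc<=2 unfiltered digest;
    detectability classifies every event derivable from the annotation.
    """
    if genome is None or genes is None:
        genome, genes = cfg.load()

    cov_rows = []
    for enzyme in cfg.enzymes:
        params = DigestParams(
            enzyme=enzyme, max_missed_cleavages=0,
            min_len=cfg.min_len, max_len=cfg.max_len,
        )
        _, per_t = digest_transcriptome(genes, genome, params)
        for gene in genes:
            for t in gene.coding_transcripts():
                protein = transcript_protein(t, genome)
                cov_rows.append(
                    {
                        "enzyme": enzyme,
                        "transcript_id": t.transcript_id,
                        "coverage": sequence_coverage(
                            per_t[t.transcript_id], protein.length
                        ),
                    }
                )
    coverage = pd.DataFrame(cov_rows)
    coverage_stats = (
        coverage.groupby("enzyme")["coverage"]
        .agg(["mean", "median"])
        .reset_index()
    )

    mc_params = DigestParams(enzyme="trypsin", max_missed_cleavages=2)
    _, per_t_mc = digest_transcriptome(
        genes, genome, mc_params, apply_length_filter=False
    )
    mc_counts = missed_cleavage_distribution(
        [p for peps in per_t_mc.values() for p in peps]
    )

    filt_params = DigestParams(
        enzyme="trypsin", max_missed_cleavages=0,
        min_len=cfg.min_len, max_len=cfg.max_len,
    )
    _, per_t_filt = digest_transcriptome(genes, genome, filt_params)
    _, per_t_raw = digest_transcriptome(
        genes, genome, filt_params, apply_length_filter=False
    )
    filt_sets = {tid: {p.sequence for p in ps} for tid, ps in per_t_filt.items()}
    raw_sets = {tid: {p.sequence for p in ps} for tid, ps in per_t_raw.items()}

    det_rows = []
    for gene in genes:
        if len(gene.transcripts) < 2:
            continue
        for e in derive_events(gene):
            matched = match_event_to_transcripts(e, gene)
            verdict = event_detectability(matched, filt_sets, raw_sets)
            det_rows.append({"event_type": e.event_type, "verdict": verdict})
    detectability = (
        pd.DataFrame(det_rows)
        .groupby(["event_type", "verdict"])
        .size()
        .reset_index(name="count")
        if det_rows
        else pd.DataFrame(columns=["event_type", "verdict", "count"])
    )

    summary = ProteomeSummary(
        coverage=coverage,
        coverage_stats=coverage_stats,
        missed_cleavage_counts=mc_counts,
        detectability=detectability,
    )
    if write_outputs:
        _write_summary(summary, Path(cfg.out_dir))
    return summary


def _write_summary(summary: ProteomeSummary, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    summary.coverage.to_csv(out / "coverage_by_transcript.tsv", sep="\t", index=False)
    summary.coverage_stats.to_csv(out / "coverage_stats.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "missed_cleavages": list(summary.missed_cleavage_counts),
            "count": list(summary.missed_cleavage_counts.values()),
        }
    ).to_csv(out / "missed_cleavage_distribution.tsv", sep="\t", index=False)
    summary.detectability.to_csv(out / "event_detectability.tsv", sep="\t", index=False)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(14, 4))
    enzymes = sorted(summary.coverage["enzyme"].unique())
    axes[0].boxplot(
        [
            summary.coverage.loc[summary.coverage["enzyme"] == e, "coverage"]
            for e in enzymes
        ],
        tick_labels=enzymes,
    )
    axes[0].set_ylabel("sequence coverage")
    axes[0].tick_params(axis="x", rotation=45)
    axes[1].bar(
        list(summary.missed_cleavage_counts),
        list(summary.missed_cleavage_counts.values()),
    )
    axes[1].set_xlabel("missed cleavages")
    axes[1].set_ylabel("peptides")
    if len(summary.detectability):
        pivot = summary.detectability.pivot_table(
            index="event_type", columns="verdict", values="count", fill_value=0
        )
        pivot.plot.bar(stacked=True, ax=axes[2], legend=True)
        axes[2].set_ylabel("events")
    fig.tight_layout()
    fig.savefig(out / "proteome_summary.svg")
    plt.close(fig)

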