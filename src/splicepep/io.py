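"""Readers and writers for the standard formats at the package boundary.

FASTA is read with Biopython; GTF is parsed with gffutils (GENCODE dialect,
attributes as ``key "value";`` pairs).  All coordinates are converted to the
internal 0-based half-open convention on read and back to 1-based inclusive
on GTF write.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import gffutils
from Bio import SeqIO

from .model import GeneModel, Genome, GenomicBlock, TranscriptModel

__all__ = [
    "read_genome",
    "write_genome_fasta",
    "read_annotation",
    "write_annotation_gtf",
    "write_proteins_fasta",
]


def read_genome(path: str | Path) -> Genome:
    """Read a multi-record FASTA into a :class:`Genome`.

    The header token before the first whitespace is the contig name;
    sequences are uppercased.  Duplicate contig names are an error.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in contigs:
            raise ValueError(f"duplicate contig name {name!r} in {path}")
        contigs[name] = str(rec.seq).upper()
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(contigs=contigs)


def write_genome_fasta(genome: Genome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome.contigs:
            fh.write(f">{name}\n")
            seq = genome.contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _gtf_frames(t: TranscriptModel) -> dict[GenomicBlock, int]:
    """GTF frame per CDS block: bases to skip to reach the next codon start."""
    frames: dict[GenomicBlock, int] = {}
    cum = 0
    first = True
    for b in t.blocks_in_transcription_order("cds"):
        if first:
            frames[b] = t.frame_of_first_cds_codon
            cum = b.width - t.frame_of_first_cds_codon
            first = False
        else:
            frames[b] = (3 - cum % 3) % 3
            cum += b.width
    return frames


def write_annotation_gtf(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as a GENCODE-style GTF (1-based inclusive)."""

    def attrs(gene: GeneModel, t: TranscriptModel | None = None) -> str:
        parts = [f'gene_id "{gene.gene_id}"']
        if t is not None:
            parts.append(f'transcript_id "{t.transcript_id}"')
        parts.append(f'gene_name "{gene.gene_name}"')
        return "; ".join(parts) + ";"

    lines = []
    for gene in sorted(genes, key=lambda g: g.gene_id):
        g_start = min(t.span.start for t in gene.transcripts)
        g_end = max(t.span.end for t in gene.transcripts)
        lines.append(
            f"{gene.contig}\tsplicepep\tgene\t{g_start + 1}\t{g_end}\t.\t"
            f"{gene.strand}\t.\t{attrs(gene)}"
        )
        for t in gene.transcripts:
            lines.append(
                f"{t.contig}\tsplicepep\ttranscript\t{t.span.start + 1}\t"
                f"{t.span.end}\t.\t{t.strand}\t.\t{attrs(gene, t)}"
            )
            for e in t.exons:
                lines.append(
                    f"{t.contig}\tsplicepep\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs(gene, t)}"
                )
            frames = _gtf_frames(t)
            for c in t.cds_blocks:
                lines.append(
                    f"{t.contig}\tsplicepep\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{t.strand}\t{frames[c]}\t{attrs(gene, t)}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read a GENCODE-style GTF into gene models.

    Coordinates become 0-based half-open.  The CDS frame of the first CDS row
    in transcription order defines ``frame_of_first_cds_codon``; a missing
    frame is assumed 0 with a warning.  Transcripts without CDS rows are kept
    as non-coding.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        if "transcript_id" not in feat.attributes:
            raise ValueError(
                f"{feat.featuretype} row at {feat.seqid}:{feat.start}-{feat.end} "
                "lacks a transcript_id attribute"
            )
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        gname = feat.attributes.get("gene_name", [gid])[0]
        rec = transcripts.setdefault(
            tid,
            {
                "gene_id": gid,
                "gene_name": gname,
                "strand": feat.strand,
                "exons": [],
                "cds": [],  # (block, frame)
            },
        )
        block = GenomicBlock(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if feat.featuretype == "exon":
            rec["exons"].append(block)
        else:
            frame = feat.frame
            if frame in (".", None, ""):
                warnings.warn(
                    f"CDS row of {tid} has no frame; assuming 0", stacklevel=2
                )
                frame = 0
            rec["cds"].append((block, int(frame)))

    genes: dict[str, list[TranscriptModel]] = {}
    gene_names: dict[str, str] = {}
    for tid, rec in transcripts.items():
        cds_sorted = sorted(rec["cds"], key=lambda cf: cf[0].start)
        cds_blocks = [b for b, _ in cds_sorted]
        for c in cds_blocks:
            if not any(
                e.start <= c.start and c.end <= e.end for e in rec["exons"]
            ):
                raise ValueError(
                    f"transcript {tid}: CDS block {c} lies outside its exons"
                )
        if cds_sorted:
            first = cds_sorted[-1] if rec["strand"] == "-" else cds_sorted[0]
            frame = first[1]
        else:
            frame = 0
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            gene_name=rec["gene_name"],
            strand=rec["strand"],
            exons=rec["exons"],
            cds_blocks=cds_blocks,
            frame_of_first_cds_codon=frame,
        )
        genes.setdefault(rec["gene_id"], []).append(t)
        gene_names[rec["gene_id"]] = rec["gene_name"]

    return sorted(
        (
            GeneModel(gene_id=gid, gene_name=gene_names[gid], transcripts=ts)
            for gid, ts in genes.items()
        ),
        key=lambda g: g.gene_id,
    )


def write_proteins_fasta(
    proteins: list, path: str | Path, width: int = 60
) -> None:
    """Write :class:`~splicepep.model.ProteinRecord` objects as FASTA."""
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.transcript_id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")
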