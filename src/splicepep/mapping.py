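"""Lift peptide residue spans to genomic coordinates through the CDS.

Residues map to CDS nucleotides (3 nt per residue), and CDS nucleotides walk
through the transcript's CDS blocks in transcription order.  A peptide whose
codons cross an exon-exon boundary maps to >= 2 genomic blocks and is
flagged junction-spanning.
"""

from __future__ import annotations

from dataclasses import dataclass

from .digestion import Peptide
from .model import Genome, GenomicBlock, TranscriptModel, reverse_complement

__all__ = [
    "MappedPeptide",
    "aa_span_to_cds",
    "cds_to_genomic",
    "map_peptide",
    "mapped_peptides_to_bed12",
]


@dataclass(frozen=True)
class MappedPeptide:
    """A peptide lifted to genomic coordinates.

    ``blocks`` are in transcription order ('-'-strand peptides therefore have
    descending genomic coordinates).
    """

    peptide: Peptide
    transcript_id: str
    blocks: tuple[GenomicBlock, ...]

    def __post_init__(self) -> None:
        total = sum(b.width for b in self.blocks)
        if total != 3 * len(self.peptide):
            raise ValueError(
                f"block widths sum to {total}, expected {3 * len(self.peptide)}"
            )

    @property
    def spans_junction(self) -> bool:
        return len(self.blocks) >= 2

    @property
    def contig(self) -> str:
        return self.blocks[0].contig

    @property
    def genomic_span(self) -> tuple[int, int]:
        """Outer (min start, max end) over all blocks."""
        return (min(b.start for b in self.blocks), max(b.end for b in self.blocks))


def aa_span_to_cds(start_res: int, end_res: int) -> tuple[int, int]:
    """1-based residue span -> 1-based inclusive CDS nucleotide interval."""
    if not (1 <= start_res <= end_res):
        raise ValueError("require 1 <= start_res <= end_res")
    return 3 * start_res - 2, 3 * end_res


def cds_to_genomic(
    t: TranscriptModel, cds_nt_interval: tuple[int, int]
) -> list[GenomicBlock]:
    """Map a 1-based inclusive CDS nt interval to genomic blocks.

    The walk goes through CDS blocks in transcription order; on the '-'
    strand, blocks descend in genomic coordinates.  The frame trim shifts
    the walk start: CDS position 1 is the (frame+1)-th base of the
    concatenated blocks.
    """
    lo, hi = cds_nt_interval
    if not (1 <= lo <= hi):
        raise ValueError("invalid CDS interval")
    # 0-based offsets into the concatenated (untrimmed) CDS walk
    lo0 = lo - 1 + t.frame_of_first_cds_codon
    hi0 = hi - 1 + t.frame_of_first_cds_codon
    total = t.cds_length()
    if hi0 >= total:
        raise ValueError(
            f"CDS interval {cds_nt_interval} exceeds CDS length "
            f"{total - t.frame_of_first_cds_codon} of {t.transcript_id}"
        )
    out: list[GenomicBlock] = []
    cum = 0
    for b in t.blocks_in_transcription_order("cds"):
        b_lo, b_hi = cum, cum + b.width - 1  # walk offsets covered by b
        cum += b.width
        a = max(lo0, b_lo)
        z = min(hi0, b_hi)
        if a > z:
            continue
        off_a, off_z = a - b_lo, z - b_lo  # offsets within the block walk
        if t.strand == "+":
            out.append(
                GenomicBlock(b.contig, b.start + off_a, b.start + off_z + 1, "+")
            )
        else:
            # transcription-order base 0 sits at genomic position b.end - 1
            out.append(
                GenomicBlock(b.contig, b.end - off_z - 1, b.end - off_a, "-")
            )
    return out


def map_peptide(t: TranscriptModel, p: Peptide) -> MappedPeptide:
    """Lift a peptide's residue span to genomic blocks on its transcript."""
    blocks = cds_to_genomic(t, aa_span_to_cds(p.start, p.end))
    return MappedPeptide(peptide=p, transcript_id=t.transcript_id, blocks=tuple(blocks))


def mapped_peptide_sequence(mp: MappedPeptide, genome: Genome) -> str:
    """Re-extract and splice a mapped peptide's coding sequence (sense strand)."""
    parts = []
    for b in mp.blocks:
        s = genome.fetch(b.contig, b.start, b.end)
        parts.append(reverse_complement(s) if b.strand == "-" else s)
    return "".join(parts)


def mapped_peptides_to_bed12(mps: list[MappedPeptide]) -> list[str]:
    """One BED12 line per mapped peptide.

    Blocks are re-sorted to ascending genomic order (the BED convention);
    name is ``transcript_id|peptide|enzyme``.
    """
    lines = []
    for mp in mps:
        blocks = sorted(mp.blocks, key=lambda b: b.start)
        chrom_start = blocks[0].start
        chrom_end = blocks[-1].end
        sizes = ",".join(str(b.width) for b in blocks)
        starts = ",".join(str(b.start - chrom_start) for b in blocks)
        name = f"{mp.transcript_id}|{mp.peptide.sequence}|{mp.peptide.enzyme}"
        lines.append(
            "\t".join(
                [
                    mp.contig,
                    str(chrom_start),
                    str(chrom_end),
                    name,
                    "0",
                    blocks[0].strand,
                    str(chrom_start),
                    str(chrom_end),
                    "0,0,0",
                    str(len(blocks)),
                    sizes,
                    starts,
                ]
            )
        )
    return lines


def parse_bed12_blocks(line: str) -> list[GenomicBlock]:
    """Recover genomic blocks from a BED12 line (ascending genomic order)."""
    f = line.rstrip("\n").split("\t")
    contig, chrom_start, strand = f[0], int(f[1]), f[5]
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    starts = [int(x) for x in f[11].rstrip(",").split(",")]
    return [
        GenomicBlock(contig, chrom_start + st, chrom_start + st + sz, strand)
        for st, sz in zip(starts, sizes)
    ]
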