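"""Genomic data model: genome, transcript structures, CDS extraction, translation.

Internal coordinates are 0-based half-open on the '+' reference strand
throughout the package.  GTF I/O converts at the boundary (1-based inclusive),
BED output is natively 0-based half-open.

A transcript is coding iff it carries CDS blocks.  The stop codon, when
annotated, is included in the CDS blocks; :func:`translate_cds` drops a single
terminal stop from the protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

__all__ = [
    "Genome",
    "GenomicBlock",
    "TranscriptModel",
    "GeneModel",
    "ProteinRecord",
    "TranslationResult",
    "spliced_cds_sequence",
    "translate_cds",
    "reverse_complement",
]

_DNA_ALPHABET = set("ACGTN")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True, order=True)
class GenomicBlock:
    """A contiguous genomic interval, 0-based half-open, with a strand."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid block {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicBlock") -> bool:
        """True iff the two half-open intervals share >= 1 nt on one contig."""
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}({self.strand})"


@dataclass
class Genome:
    """In-memory genome: contig name -> uppercase DNA string (ACGTN)."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} has an empty sequence")

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the sequence of the 0-based half-open interval [start, end)."""
        seq = self.contigs[contig]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(
                f"interval {start}-{end} out of range for contig "
                f"{contig!r} of length {len(seq)}"
            )
        return seq[start:end]

    def fetch_block(self, block: GenomicBlock) -> str:
        """Strand-aware fetch: '-' blocks are reverse-complemented."""
        s = self.fetch(block.contig, block.start, block.end)
        return reverse_complement(s) if block.strand == "-" else s

    def contig_length(self, contig: str) -> int:
        return len(self.contigs[contig])


@dataclass
class TranscriptModel:
    """One transcript isoform: ordered exon blocks plus optional CDS blocks.

    ``exons`` and ``cds_blocks`` are sorted by ascending genomic start
    regardless of strand; transcription order is derived from ``strand``.
    ``frame_of_first_cds_codon`` is the number of bases to trim from the 5'
    end of the spliced CDS so that position 1 starts a codon (GTF frame of
    the first CDS row in transcription order).
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    strand: str
    exons: list[GenomicBlock]
    cds_blocks: list[GenomicBlock] = field(default_factory=list)
    frame_of_first_cds_codon: int = 0

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda b: b.start)
        self.cds_blocks = sorted(self.cds_blocks, key=lambda b: b.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {a} and {b}"
                )
        for c in self.cds_blocks:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ValueError(
                    f"{self.transcript_id}: CDS block {c} not contained in any exon"
                )
        if self.frame_of_first_cds_codon not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def is_coding(self) -> bool:
        return bool(self.cds_blocks)

    @property
    def span(self) -> GenomicBlock:
        return GenomicBlock(
            self.contig, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def cds_length(self) -> int:
        """Total CDS width in nt, before the frame trim."""
        return sum(b.width for b in self.cds_blocks)

    def blocks_in_transcription_order(
        self, which: str = "cds"
    ) -> list[GenomicBlock]:
        blocks = self.cds_blocks if which == "cds" else self.exons
        return list(reversed(blocks)) if self.strand == "-" else list(blocks)

    def spliced_exon_sequence(self, genome: Genome) -> str:
        """The mature (cDNA) sequence: exons in transcription order."""
        parts = []
        for b in self.blocks_in_transcription_order("exon"):
            parts.append(genome.fetch_block(replace(b, strand=self.strand)))
        return "".join(parts)


@dataclass
class GeneModel:
    """A gene: >= 1 transcript on one contig and strand."""

    gene_id: str
    gene_name: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        contigs = {t.contig for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(contigs) > 1 or len(strands) > 1:
            raise ValueError(
                f"gene {self.gene_id}: transcripts span multiple contigs/strands"
            )
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise ValueError(
                    f"transcript {t.transcript_id} carries gene_id {t.gene_id}, "
                    f"expected {self.gene_id}"
                )
        self.transcripts = sorted(self.transcripts, key=lambda t: t.transcript_id)

    @property
    def contig(self) -> str:
        return self.transcripts[0].contig

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    def coding_transcripts(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.is_coding]

    def get_transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


@dataclass(frozen=True)
class ProteinRecord:
    """A translated protein tied to its transcript of origin."""

    transcript_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranslationResult:
    """Protein plus flags describing how translation terminated."""

    sequence: str
    truncated_at_internal_stop: bool = False
    leftover_nt: int = 0
    had_terminal_stop: bool = False


def spliced_cds_sequence(t: TranscriptModel, genome: Genome) -> str:
    """Concatenate CDS block sequences in transcription order.

    On the '-' strand, blocks are taken in descending genomic order and each
    is reverse-complemented.  The leading ``frame_of_first_cds_codon`` bases
    are trimmed so position 1 of the returned string starts a codon.
    """
    if not t.is_coding:
        raise ValueError(f"transcript {t.transcript_id} is non-coding")
    parts = []
    for b in t.blocks_in_transcription_order("cds"):
        seq = genome.fetch(b.contig, b.start, b.end)
        parts.append(reverse_complement(seq) if t.strand == "-" else seq)
    cds = "".join(parts)[t.frame_of_first_cds_codon :]
    if len(cds) < 3:
        raise ValueError(
            f"transcript {t.transcript_id}: CDS shorter than one codon after "
            "frame trimming"
        )
    return cds


def translate_cds(seq: str) -> TranslationResult:
    """Translate a CDS with the standard genetic code.

    A single terminal stop codon is dropped; an internal stop truncates the
    protein at that point and sets ``truncated_at_internal_stop``; 1-2
    trailing leftover nt are ignored (``leftover_nt``); codons containing N
    translate to 'X'.  Non-ACGTN symbols are an error.
    """
    if len(seq) < 3:
        raise ValueError("CDS shorter than one codon")
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"non-ACGTN symbols in CDS: {sorted(bad)}")
    leftover = len(seq) % 3
    if leftover:
        warnings.warn(
            f"CDS length {len(seq)} not a multiple of 3; "
            f"ignoring {leftover} trailing nt",
            stacklevel=2,
        )
    aa = str(Seq(seq[: len(seq) - leftover]).translate())
    terminal_stop = aa.endswith("*")
    if terminal_stop:
        aa = aa[:-1]
    truncated = "*" in aa
    if truncated:
        aa = aa.split("*", 1)[0]
    return TranslationResult(
        sequence=aa,
        truncated_at_internal_stop=truncated,
        leftover_nt=leftover,
        had_terminal_stop=terminal_stop,
    )


def transcript_protein(t: TranscriptModel, genome: Genome) -> ProteinRecord:
    """Convenience: spliced CDS -> translated :class:`ProteinRecord`."""
    res = translate_cds(spliced_cds_sequence(t, genome))
    return ProteinRecord(transcript_id=t.transcript_id, sequence=res.sequence)
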