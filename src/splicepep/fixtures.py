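"""Deterministic synthetic genome + annotation exercising all five AS types.

The generator emits one multi-isoform gene per alternative-splicing event
type (SE, RI, MXE, A5SS, A3SS), a skipped exon placed entirely in a 3'UTR,
and a gene whose only event-differential tryptic fragments are 3-5 residues
long.  One gene (the retained-intron pair) sits on the '-' strand.  Each
gene lives on its own contig; coding sequences begin with ATG and end with a
stop codon.

Proteins are designed first (so that specific tryptic peptides are planted
with known specificity and length) and reverse-translated with a fixed codon
table; introns, UTRs and intergenic padding are seeded-random DNA.  Random
segments are scrubbed of ATG so that ORF prediction on any spliced
transcript sequence recovers exactly the annotated CDS.

An extra "novel" exon is planted inside an intron of the SE gene but omitted
from the annotation; :attr:`Fixture.planted` carries its coordinates and the
novel cDNA built from it, the substrate for the novel-isoform pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import write_annotation_gtf, write_genome_fasta
from .model import (
    GeneModel,
    Genome,
    GenomicBlock,
    TranscriptModel,
    reverse_complement,
)

__all__ = ["FixtureConfig", "Fixture", "generate_fixture", "mirror_fixture"]

#: one fixed codon per amino acid (plus TAA as the only stop used)
CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAC", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
STOP = "TAA"


def _rt(aa: str) -> str:
    """Reverse-translate a protein segment with the fixed codon table."""
    return "".join(CODON[a] for a in aa)


@dataclass(frozen=True)
class FixtureConfig:
    """Sizes of the random scaffolding around the designed exons (nt)."""

    pad: int = 120
    intron: int = 80
    utr5: int = 21
    utr3: int = 24


@dataclass(frozen=True)
class PlantedEvent:
    """Ground truth for one designed AS event."""

    gene_id: str
    event_type: str
    alt_regions: tuple[GenomicBlock, ...]
    inclusion: str  # transcript_id containing the alternative region(s)[0]
    exclusion: str
    expected_verdict: str  # detectable | no_differential_peptide | length_out_of_range


@dataclass
class Fixture:
    """A generated genome + gene models plus the planted ground truth."""

    seed: int
    genome: Genome
    genes: list[GeneModel]
    events: dict[str, PlantedEvent]  # keyed by gene_id
    planted: dict[str, object] = field(default_factory=dict)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def write(self, outdir: str | Path) -> tuple[Path, Path]:
        """Write genome FASTA and annotation GTF; returns their paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "fixture_genome.fa"
        gtf = outdir / "fixture_annotation.gtf"
        write_genome_fasta(self.genome, fasta)
        write_annotation_gtf(self.genes, gtf)
        return fasta, gtf


class _Builder:
    """Assemble one contig left-to-right in sense (transcription) orientation."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.parts: list[str] = []
        self.pos = 0

    def random(self, n: int) -> tuple[int, int]:
        seq = "".join(self.rng.choice(list("ACGT"), size=n))
        while "ATG" in seq:  # keep spurious start codons out of cDNA/UTRs
            seq = seq.replace("ATG", "ATC")
        return self.add(seq)

    def add(self, seq: str) -> tuple[int, int]:
        start = self.pos
        self.parts.append(seq)
        self.pos += len(seq)
        return start, self.pos

    @property
    def sequence(self) -> str:
        return "".join(self.parts)


def _span(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int]:
    return (min(a[0], b[0]), max(a[1], b[1]))


def _flip(iv: tuple[int, int], length: int) -> tuple[int, int]:
    return (length - iv[1], length - iv[0])


def _make_gene(
    contig: str,
    strand: str,
    builder: _Builder,
    gene_id: str,
    gene_name: str,
    exon_specs: dict[str, tuple[tuple[int, int], tuple[int, int] | None]],
    isoforms: dict[str, list[str]],
) -> tuple[str, GeneModel, dict[str, GenomicBlock]]:
    """Finish a contig and build the gene model.

    ``exon_specs``: exon name -> (exon sense-interval, cds sense-interval or
    None).  For '-' strand genes, the whole contig is reverse-complemented
    and every interval flipped.
    """
    seq = builder.sequence
    length = len(seq)
    if strand == "-":
        seq = reverse_complement(seq)

    def block(iv: tuple[int, int]) -> GenomicBlock:
        s, e = _flip(iv, length) if strand == "-" else iv
        return GenomicBlock(contig, s, e, strand)

    named: dict[str, GenomicBlock] = {}
    transcripts = []
    for tid, exon_names in isoforms.items():
        exons, cds = [], []
        for name in exon_names:
            exon_iv, cds_iv = exon_specs[name]
            exons.append(block(exon_iv))
            if cds_iv is not None:
                cds.append(block(cds_iv))
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                gene_name=gene_name,
                strand=strand,
                exons=exons,
                cds_blocks=cds,
            )
        )
    for name, (exon_iv, _) in exon_specs.items():
        named[name] = block(exon_iv)
    gene = GeneModel(gene_id=gene_id, gene_name=gene_name, transcripts=transcripts)
    return seq, gene, named


# -- designed protein segments -------------------------------------------------

SE_E1_AA = "MTEVLKSQ"
SE_CASSETTE_AA = "LNDAGVTR"
SE_E3_AA = "EILNSGKDSSTNPLEIKAVNESLMDHGQSTIEPLNRGVDESITNLKSEPTMANDE"
SE_NOVEL_AA = "GLNVDDSSTK"

RI_X1_AA = "MAGELVSR"
RI_INTRON_AA = "SVDNLGTAE"
RI_X2_AA = "TNDLIAGKELDNSAVTGHMQ"

A5_E1_AA = "MLDSTNAVGEGK"
A5_EXT_AA = "LNTDSV"
A5_E2_AA = "AGDHERSLTVNQDGE"

A3_E1_AA = "MSDNLVAGTEK"
A3_EXT_AA = "QSVLDA"
A3_E2_AA = "GENLTSRADSVQME"

MXE_E1_AA = "MAVSELDGSSK"
MXE_A_AA = "LDNTAGVR"
MXE_B_AA = "ESQHMTGK"
MXE_E3_AA = "SLIDGHEANTVSSQEKAGTLDNE"

U3_CDS_AA = "MGSTDLNVAEKSLDGENTQR"

SH_E1_AA = "MSTNLVAESGK"
SH_CASSETTE_AA = "VTAKLDK"
SH_E3_AA = "ELGNDHMSAQTVIE"


def generate_fixture(seed: int = 1, config: FixtureConfig | None = None) -> Fixture:
    """Build the synthetic genome + annotation, deterministic per seed."""
    cfg = config or FixtureConfig()
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    genes: list[GeneModel] = []
    events: dict[str, PlantedEvent] = {}
    planted: dict[str, object] = {}

    # --- SE gene ('+', cassette exon, planted novel exon in intron 2) --------
    b = _Builder(rng)
    b.random(cfg.pad)
    utr5 = b.random(cfg.utr5)
    cds1 = b.add(_rt(SE_E1_AA))
    e1 = _span(utr5, cds1)
    b.random(cfg.intron)
    cds2 = b.add(_rt(SE_CASSETTE_AA))
    e2 = cds2
    b.random(45)
    novel = b.add(_rt(SE_NOVEL_AA))
    b.random(45)
    cds3 = b.add(_rt(SE_E3_AA) + STOP)
    utr3 = b.random(cfg.utr3)
    e3 = _span(cds3, utr3)
    b.random(cfg.pad)
    seq, gene, named = _make_gene(
        "chrSE", "+", b, "GSE", "SEG1",
        {"E1": (e1, cds1), "E2": (e2, cds2), "E3": (e3, cds3), "NOV": (novel, novel)},
        {"T_SE_INC": ["E1", "E2", "E3"], "T_SE_EXC": ["E1", "E3"]},
    )
    contigs["chrSE"] = seq
    genes.append(gene)
    events["GSE"] = PlantedEvent(
        "GSE", "SE", (named["E2"],), "T_SE_INC", "T_SE_EXC", "detectable"
    )
    inc = gene.get_transcript("T_SE_INC")
    planted.update(
        {
            "cassette_peptide": "SQ" + SE_CASSETTE_AA,
            "exclusion_junction_peptide": "SQ" + "EILNSGK",
            "shared_query_peptide": "DSSTNPLEIK",
            "novel_exon": named["NOV"],
            "novel_peptide": SE_NOVEL_AA,
            "novel_exon_chain": [
                inc.exons[0], inc.exons[1], named["NOV"], inc.exons[2]
            ],
        }
    )
    planted["novel_cdna"] = "".join(
        contigs["chrSE"][blk.start : blk.end] for blk in planted["novel_exon_chain"]
    )

    # --- RI gene ('-', retained intron) --------------------------------------
    b = _Builder(rng)
    b.random(cfg.pad)
    utr5 = b.random(cfg.utr5)
    cds_x1 = b.add(_rt(RI_X1_AA))
    x1 = _span(utr5, cds_x1)
    intron = b.add(_rt(RI_INTRON_AA))  # in-frame, stop-free designed intron
    cds_x2 = b.add(_rt(RI_X2_AA) + STOP)
    utr3 = b.random(cfg.utr3)
    x2 = _span(cds_x2, utr3)
    b.random(cfg.pad)
    retained_exon = _span(x1, x2)
    retained_cds = _span(cds_x1, cds_x2)
    seq, gene, named = _make_gene(
        "chrRI", "-", b, "GRI", "RIG1",
        {
            "X1": (x1, cds_x1),
            "X2": (x2, cds_x2),
            "RET": (retained_exon, retained_cds),
            "INTRON": (intron, None),
        },
        {"T_RI_RET": ["RET"], "T_RI_SPL": ["X1", "X2"]},
    )
    contigs["chrRI"] = seq
    genes.append(gene)
    events["GRI"] = PlantedEvent(
        "GRI", "RI", (named["INTRON"],), "T_RI_RET", "T_RI_SPL", "detectable"
    )

    # --- A5SS gene ('+', alternative donor: long vs short first exon) --------
    b = _Builder(rng)
    b.random(cfg.pad)
    utr5 = b.random(cfg.utr5)
    cds_common = b.add(_rt(A5_E1_AA))
    ext = b.add(_rt(A5_EXT_AA))
    e1_short = _span(utr5, cds_common)
    e1_long = _span(utr5, ext)
    b.random(cfg.intron)
    cds_e2 = b.add(_rt(A5_E2_AA) + STOP)
    utr3 = b.random(cfg.utr3)
    e2 = _span(cds_e2, utr3)
    b.random(cfg.pad)
    seq, gene, named = _make_gene(
        "chrA5", "+", b, "GA5", "A5G1",
        {
            "E1L": (e1_long, _span(cds_common, ext)),
            "E1S": (e1_short, cds_common),
            "E2": (e2, cds_e2),
            "EXT": (ext, None),
        },
        {"T_A5_LONG": ["E1L", "E2"], "T_A5_SHORT": ["E1S", "E2"]},
    )
    contigs["chrA5"] = seq
    genes.append(gene)
    events["GA5"] = PlantedEvent(
        "GA5", "A5SS", (named["EXT"],), "T_A5_LONG", "T_A5_SHORT", "detectable"
    )

    # --- A3SS gene ('+', alternative acceptor: long vs short second exon) ----
    b = _Builder(rng)
    b.random(cfg.pad)
    utr5 = b.random(cfg.utr5)
    cds_e1 = b.add(_rt(A3_E1_AA))
    e1 = _span(utr5, cds_e1)
    b.random(cfg.intron)
    ext = b.add(_rt(A3_EXT_AA))
    cds_common = b.add(_rt(A3_E2_AA) + STOP)
    utr3 = b.random(cfg.utr3)
    e2_long = _span(ext, utr3)
    e2_short = _span(cds_common, utr3)
    b.random(cfg.pad)
    seq, gene, named = _make_gene(
        "chrA3", "+", b, "GA3", "A3G1",
        {
            "E1": (e1, cds_e1),
            "E2L": (e2_long, _span(ext, cds_common)),
            "E2S": (e2_short, cds_common),
            "EXT": (ext, None),
        },
        {"T_A3_LONG": ["E1", "E2L"], "T_A3_SHORT": ["E1", "E2S"]},
    )
    contigs["chrA3"] = seq
    genes.append(gene)
    events["GA3"] = PlantedEvent(
        "GA3", "A3SS", (named["EXT"],), "T_A3_LONG", "T_A3_SHORT", "detectable"
    )

    # --- MXE gene ('+', mutually exclusive middle exons) ----------------------
    b = _Builder(rng)
    b.random(cfg.pad)
    utr5 = b.random(cfg.utr5)
    cds_e1 = b.add(_rt(MXE_E1_AA))
    e1 = _span(utr5, cds_e1)
    b.random(cfg.intron)
    ma = b.add(_rt(MXE_A_AA))
    b.random(60)
    mb = b.add(_rt(MXE_B_AA))
    b.random(cfg.intron)
    cds_e3 = b.add(_rt(MXE_E3_AA) + STOP)
    utr3 = b.random(cfg.utr3)
    e3 = _span(cds_e3, utr3)
    b.random(cfg.pad)
    seq, gene, named = _make_gene(
        "chrMXE", "+", b, "GMXE", "MXEG1",
        {
            "E1": (e1, cds_e1),
            "MA": (ma, ma),
            "MB": (mb, mb),
            "E3": (e3, cds_e3),
        },
        {"T_MXE_A": ["E1", "MA", "E3"], "T_MXE_B": ["E1", "MB", "E3"]},
    )
    contigs["chrMXE"] = seq
    genes.append(gene)
    events["GMXE"] = PlantedEvent(
        "GMXE", "MXE", (named["MA"], named["MB"]), "T_MXE_A", "T_MXE_B", "detectable"
    )

    # --- 3'UTR SE gene ('+', event entirely non-coding) -----------------------
    b = _Builder(rng)
    b.random(cfg.pad)
    utr5 = b.random(cfg.utr5)
    cds_e1 = b.add(_rt(U3_CDS_AA) + STOP)
    utr3a = b.random(21)
    e1 = _span(utr5, utr3a)
    b.random(65)
    ucass = b.random(27)
    b.random(55)
    ulast = b.random(33)
    b.random(cfg.pad)
    seq, gene, named = _make_gene(
        "chrU3", "+", b, "GU3", "U3G1",
        {
            "E1": (e1, cds_e1),
            "UCASS": (ucass, None),
            "ULAST": (ulast, None),
        },
        {"T_U3_INC": ["E1", "UCASS", "ULAST"], "T_U3_EXC": ["E1", "ULAST"]},
    )
    contigs["chrU3"] = seq
    genes.append(gene)
    events["GU3"] = PlantedEvent(
        "GU3", "SE", (named["UCASS"],), "T_U3_INC", "T_U3_EXC",
        "no_differential_peptide",
    )

    # --- short-fragment SE gene ('+', differential peptides all 3-5 aa) ------
    b = _Builder(rng)
    b.random(cfg.pad)
    utr5 = b.random(cfg.utr5)
    cds_e1 = b.add(_rt(SH_E1_AA))
    e1 = _span(utr5, cds_e1)
    b.random(cfg.intron)
    cds_e2 = b.add(_rt(SH_CASSETTE_AA))
    b.random(cfg.intron)
    cds_e3 = b.add(_rt(SH_E3_AA) + STOP)
    utr3 = b.random(cfg.utr3)
    e3 = _span(cds_e3, utr3)
    b.random(cfg.pad)
    seq, gene, named = _make_gene(
        "chrSH", "+", b, "GSH", "SHG1",
        {"E1": (e1, cds_e1), "E2": (cds_e2, cds_e2), "E3": (e3, cds_e3)},
        {"T_SH_INC": ["E1", "E2", "E3"], "T_SH_EXC": ["E1", "E3"]},
    )
    contigs["chrSH"] = seq
    genes.append(gene)
    events["GSH"] = PlantedEvent(
        "GSH", "SE", (named["E2"],), "T_SH_INC", "T_SH_EXC", "length_out_of_range"
    )
    planted["short_differential_peptides"] = {"VTAK", "LDK"}

    return Fixture(
        seed=seed,
        genome=Genome(contigs=contigs),
        genes=genes,
        events=events,
        planted=planted,
    )


def mirror_fixture(genome: Genome, genes: list[GeneModel]) -> tuple[Genome, list[GeneModel]]:
    """Reverse-complement every contig and flip all annotations.

    Coordinates become mirror images (start' = L - end) and strands swap.
    Protein sequences and peptide sets are invariant under this
    transformation; it is the symmetry check for all coordinate arithmetic.
    """
    lengths = {name: len(seq) for name, seq in genome.contigs.items()}
    mirrored_genome = Genome(
        contigs={name: reverse_complement(seq) for name, seq in genome.contigs.items()}
    )

    def flip_block(blk: GenomicBlock) -> GenomicBlock:
        length = lengths[blk.contig]
        return GenomicBlock(
            blk.contig,
            length - blk.end,
            length - blk.start,
            "-" if blk.strand == "+" else "+",
        )

    mirrored_genes = []
    for gene in genes:
        transcripts = [
            TranscriptModel(
                transcript_id=t.transcript_id,
                gene_id=t.gene_id,
                gene_name=t.gene_name,
                strand="-" if t.strand == "+" else "+",
                exons=[flip_block(e) for e in t.exons],
                cds_blocks=[flip_block(c) for c in t.cds_blocks],
                frame_of_first_cds_codon=t.frame_of_first_cds_codon,
            )
            for t in gene.transcripts
        ]
        mirrored_genes.append(
            GeneModel(gene_id=gene.gene_id, gene_name=gene.gene_name, transcripts=transcripts)
        )
    return mirrored_genome, mirrored_genes
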