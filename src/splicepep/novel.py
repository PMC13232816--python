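"""Novel-isoform pipeline: ORF calling, placement, reference comparison.

A user cDNA (from long-read sequencing, de-novo assembly, or isoform-level
AS tools) is turned into a placed transcript model by (a) a user-supplied
exon structure (GTF/BED12-style blocks, validated base-by-base against the
cDNA) or (b) an exact-match search against annotated transcripts.  External
spliced aligners are deliberately not reimplemented; an unplaced sequence is
reported as such so the caller can fall back to one.

The ORF call is a forward-frame scan (cDNA is assumed stranded); the
longest complete ATG..stop span wins, ties broken 5'-most.
"""

from __future__ import annotations

from dataclasses import dataclass

from .digestion import DigestParams, Peptide, PeptideIndex, digest
from .model import (
    GeneModel,
    Genome,
    GenomicBlock,
    TranscriptModel,
    reverse_complement,
    transcript_protein,
    translate_cds,
)
from .specificity import UNIQUE, classify_specificity

__all__ = [
    "OrfCall",
    "NovelTranscript",
    "predict_orf",
    "place_transcript",
    "similar_reference_isoforms",
    "novel_specific_peptides",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfCall:
    """An open reading frame in a cDNA (1-based, end includes the stop)."""

    start_nt: int
    end_nt: int
    protein: str
    complete: bool

    def __post_init__(self) -> None:
        if (self.end_nt - self.start_nt + 1) % 3:
            raise ValueError("ORF length must be divisible by 3")


@dataclass
class NovelTranscript:
    """A placed novel isoform: transcript model + ORF + provenance."""

    model: TranscriptModel
    orf: OrfCall
    provenance: str  # user_gtf | exact_match | external_aligner

    @property
    def transcript_id(self) -> str:
        return self.model.transcript_id


def predict_orf(
    cdna: str, min_codons: int = 30, scan_reverse: bool = False
) -> OrfCall | None:
    """Longest complete ATG..stop ORF across the three forward frames.

    ``min_codons`` bounds the encoded protein length of an acceptable
    complete ORF.  If no complete ORF qualifies, the longest ATG-initiated
    open span is returned flagged incomplete.  No ATG at all -> None.
    With ``scan_reverse``, the reverse complement is scanned as well and the
    longer call wins.
    """
    cdna = cdna.upper()
    best = _scan_forward(cdna, min_codons)
    if scan_reverse:
        rc_best = _scan_forward(reverse_complement(cdna), min_codons)
        if rc_best is not None and (
            best is None or len(rc_best.protein) > len(best.protein)
        ):
            best = rc_best
    return best


def _scan_forward(cdna: str, min_codons: int) -> OrfCall | None:
    n = len(cdna)
    complete: list[OrfCall] = []
    incomplete: list[OrfCall] = []
    for frame in range(3):
        i = frame
        while i + 3 <= n:
            if cdna[i : i + 3] != "ATG":
                i += 3
                continue
            j = i + 3
            stop_at = None
            while j + 3 <= n:
                if cdna[j : j + 3] in _STOPS:
                    stop_at = j
                    break
                j += 3
            if stop_at is not None:
                protein = translate_cds(cdna[i : stop_at + 3]).sequence
                complete.append(OrfCall(i + 1, stop_at + 3, protein, True))
                i = stop_at + 3  # next ATG in this frame after the stop
            else:
                span = (n - i) // 3 * 3
                if span >= 3:
                    protein = translate_cds(cdna[i : i + span]).sequence
                    incomplete.append(OrfCall(i + 1, i + span, protein, False))
                break
    qualified = [o for o in complete if len(o.protein) >= min_codons]
    pool = qualified or incomplete
    if not pool:
        pool = complete  # an ATG exists but no ORF meets the threshold
    if not pool:
        return None
    return min(pool, key=lambda o: (-len(o.protein), o.start_nt))


def _project_orf(
    exons: list[GenomicBlock], strand: str, orf: OrfCall
) -> list[GenomicBlock]:
    """Map 1-based cDNA interval [start_nt, end_nt] through exon blocks."""
    order = list(reversed(exons)) if strand == "-" else list(exons)
    lo0, hi0 = orf.start_nt - 1, orf.end_nt - 1
    out = []
    cum = 0
    for b in order:
        b_lo, b_hi = cum, cum + b.width - 1
        cum += b.width
        a, z = max(lo0, b_lo), min(hi0, b_hi)
        if a > z:
            continue
        oa, oz = a - b_lo, z - b_lo
        if strand == "+":
            out.append(GenomicBlock(b.contig, b.start + oa, b.start + oz + 1, strand))
        else:
            out.append(GenomicBlock(b.contig, b.end - oz - 1, b.end - oa, strand))
    return sorted(out, key=lambda b: b.start)


def place_transcript(
    cdna: str,
    genes: list[GeneModel],
    genome: Genome,
    structure: list[GenomicBlock] | None = None,
    transcript_id: str = "NOVEL_1",
    min_codons: int = 30,
) -> NovelTranscript | None:
    """Place a cDNA on the genome and call its CDS.

    With ``structure`` (user exon blocks, all one contig/strand), the spliced
    exonic sequence must equal the cDNA exactly; the first mismatch is
    reported otherwise.  Without it, an exact-match search adopts the exon
    chain of an annotated transcript whose spliced sequence equals or
    contains the cDNA.  Returns None ("unplaced") when no exact match
    exists — use an external spliced aligner and pass its structure.
    """
    cdna = cdna.upper()
    if structure is not None:
        strand = structure[0].strand
        exons = sorted(structure, key=lambda b: b.start)
        order = list(reversed(exons)) if strand == "-" else exons
        spliced = "".join(
            reverse_complement(genome.fetch(b.contig, b.start, b.end))
            if strand == "-"
            else genome.fetch(b.contig, b.start, b.end)
            for b in order
        )
        if spliced != cdna:
            pos = next(
                (i for i, (x, y) in enumerate(zip(spliced, cdna)) if x != y),
                min(len(spliced), len(cdna)),
            )
            raise ValueError(
                f"exonic sequence does not match the cDNA (lengths "
                f"{len(spliced)} vs {len(cdna)}; first mismatch at cDNA "
                f"position {pos + 1})"
            )
        provenance = "user_gtf"
    else:
        exons = None
        provenance = "exact_match"
        for gene in genes:
            for t in gene.transcripts:
                spliced = t.spliced_exon_sequence(genome)
                if spliced == cdna:
                    exons = list(t.exons)
                    strand = t.strand
                    break
                offset = spliced.find(cdna)
                if offset != -1:
                    exons = _trim_chain(t, offset, offset + len(cdna))
                    strand = t.strand
                    break
            if exons is not None:
                break
        if exons is None:
            return None

    orf = predict_orf(cdna, min_codons=min_codons)
    cds_blocks = _project_orf(exons, strand, orf) if orf else []
    gene_id = _host_gene(exons, genes)
    model = TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id or transcript_id,
        gene_name=gene_id or transcript_id,
        strand=strand,
        exons=exons,
        cds_blocks=cds_blocks,
    )
    return NovelTranscript(model=model, orf=orf, provenance=provenance)


def _trim_chain(t: TranscriptModel, lo: int, hi: int) -> list[GenomicBlock]:
    """Exon chain of the transcript restricted to cDNA offsets [lo, hi)."""
    out = []
    cum = 0
    for b in t.blocks_in_transcription_order("exon"):
        b_lo, b_hi = cum, cum + b.width
        cum += b.width
        a, z = max(lo, b_lo), min(hi, b_hi)
        if a >= z:
            continue
        oa, oz = a - b_lo, z - b_lo
        if t.strand == "+":
            out.append(GenomicBlock(b.contig, b.start + oa, b.start + oz, "+"))
        else:
            out.append(GenomicBlock(b.contig, b.end - oz, b.end - oa, "-"))
    return sorted(out, key=lambda b: b.start)


def _host_gene(exons: list[GenomicBlock], genes: list[GeneModel]) -> str | None:
    span_start = min(b.start for b in exons)
    span_end = max(b.end for b in exons)
    for gene in genes:
        for t in gene.transcripts:
            if (
                t.contig == exons[0].contig
                and t.span.start < span_end
                and span_start < t.span.end
            ):
                return gene.gene_id
    return None


def _exonic_intervals(blocks: list[GenomicBlock]) -> list[tuple[int, int]]:
    ivs = sorted((b.start, b.end) for b in blocks)
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _interval_jaccard(a: list[GenomicBlock], b: list[GenomicBlock]) -> float:
    ia, ib = _exonic_intervals(a), _exonic_intervals(b)
    inter = 0
    for s1, e1 in ia:
        for s2, e2 in ib:
            inter += max(0, min(e1, e2) - max(s1, s2))
    total_a = sum(e - s for s, e in ia)
    total_b = sum(e - s for s, e in ib)
    union = total_a + total_b - inter
    return inter / union if union else 0.0


def similar_reference_isoforms(
    n: NovelTranscript, genes: list[GeneModel], k: int
) -> list[TranscriptModel]:
    """Top-k reference isoforms by Jaccard over exonic genomic base coverage.

    Candidates are same-contig, same-strand transcripts overlapping the
    novel transcript's span; ties break lexicographically on transcript_id.
    """
    span = n.model.span
    scored = []
    for gene in genes:
        for t in gene.transcripts:
            if t.contig != span.contig or t.strand != span.strand:
                continue
            if not (t.span.start < span.end and span.start < t.span.end):
                continue
            scored.append(
                (-_interval_jaccard(n.model.exons, t.exons), t.transcript_id, t)
            )
    scored.sort(key=lambda x: (x[0], x[1]))
    return [t for _, _, t in scored[: max(k, 0)]]


def novel_specific_peptides(
    n: NovelTranscript,
    refs: list[TranscriptModel],
    genome: Genome,
    params: DigestParams,
) -> list[Peptide]:
    """Peptides of the novel isoform absent from every reference digest.

    The novel protein (from the ORF call) and all coding references are
    digested with the same parameters; peptides labeled *unique* to the
    novel isoform across the {novel} u refs selection are returned as
    position-anchored records.
    """
    if n.orf is None or not n.orf.protein:
        raise ValueError("novel transcript is non-coding; no peptides to compare")
    index = PeptideIndex()
    novel_peps = digest(
        n.orf.protein, params, apply_length_filter=True,
        transcript_id=n.transcript_id,
    )
    index.scope.add(n.transcript_id)
    for p in novel_peps:
        index.add(p.sequence, n.transcript_id)
    for t in refs:
        if not t.is_coding:
            continue
        protein = transcript_protein(t, genome).sequence
        index.scope.add(t.transcript_id)
        for p in digest(protein, params, apply_length_filter=True):
            index.add(p.sequence, t.transcript_id)
    labels = classify_specificity(index, index.scope)
    return [
        p
        for p in novel_peps
        if labels.get(p.sequence) == UNIQUE
        and index.transcripts_of(p.sequence) == {n.transcript_id}
    ]
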