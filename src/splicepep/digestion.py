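"""In-silico proteolytic digestion with six proteases and missed cleavages.

Cleavage rules are data, not code: each protease is a residue set plus a cut
terminus ('C' = cut after the residue, 'N' = cut before it) and an optional
set of blocking residues (e.g., proline after K/R suppresses tryptic
cleavage).  The rules are the high-specificity ExPASy defaults; the
low-specificity chymotrypsin (adds L) and GluC-with-D variants are available
as named alternatives.

Ambiguity handling: 'X' (from N-containing codons) and 'U' (selenocysteine)
never cleave and never block.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

from .model import GeneModel, Genome, spliced_cds_sequence, translate_cds

__all__ = [
    "ProteaseRule",
    "PROTEASES",
    "protease_rule",
    "DigestParams",
    "Peptide",
    "PeptideIndex",
    "cleavage_sites",
    "digest",
    "missed_cleavage_distribution",
    "digest_transcriptome",
]


@dataclass(frozen=True)
class ProteaseRule:
    name: str
    cleave_residues: frozenset[str]
    terminus: str  # 'C' or 'N'
    blocked_next: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.cleave_residues:
            raise ValueError("cleave_residues must be non-empty")
        if self.terminus not in ("C", "N"):
            raise ValueError("terminus must be 'C' or 'N'")


def _rule(name, residues, terminus, blocked=""):
    return ProteaseRule(name, frozenset(residues), terminus, frozenset(blocked))


PROTEASES: dict[str, ProteaseRule] = {
    "trypsin": _rule("trypsin", "KR", "C", "P"),
    "lysc": _rule("lysc", "K", "C"),
    "lysn": _rule("lysn", "K", "N"),
    "aspn": _rule("aspn", "D", "N"),
    "chymotrypsin": _rule("chymotrypsin", "FYW", "C", "P"),
    "gluc": _rule("gluc", "E", "C"),
    # documented lower-specificity variants
    "chymotrypsin-low": _rule("chymotrypsin-low", "FYWL", "C", "P"),
    "gluc-de": _rule("gluc-de", "ED", "C"),
}

#: The six standard proteases of the peptide-database builder.
STANDARD_ENZYMES = ["trypsin", "lysc", "lysn", "aspn", "chymotrypsin", "gluc"]


def protease_rule(name: str) -> ProteaseRule:
    try:
        return PROTEASES[name]
    except KeyError:
        raise ValueError(
            f"unknown protease {name!r}; known: {sorted(PROTEASES)}"
        ) from None


@dataclass(frozen=True)
class DigestParams:
    """Digestion parameters.

    ``max_missed_cleavages`` defaults to 0 (full digestion); the companion
    database uses 2.  The 6-60 residue window is the default MS-detectable
    length range.
    """

    enzyme: str = "trypsin"
    max_missed_cleavages: int = 0
    min_len: int = 6
    max_len: int = 60

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if not (0 <= self.min_len <= self.max_len):
            raise ValueError("require 0 <= min_len <= max_len")
        protease_rule(self.enzyme)

    @property
    def rule(self) -> ProteaseRule:
        return protease_rule(self.enzyme)


@dataclass(frozen=True)
class Peptide:
    """A proteolytic fragment anchored at its 1-based residue span."""

    sequence: str
    start: int  # 1-based first residue in the parent protein
    end: int  # 1-based last residue, inclusive
    missed_cleavages: int
    enzyme: str
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"span {self.start}-{self.end} inconsistent with sequence "
                f"length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def cleavage_sites(protein: str, rule: ProteaseRule) -> list[int]:
    """Cut positions: a site ``i`` means a cut after 1-based residue ``i``.

    For a C-terminal rule, residue i must be a cleavage residue and residue
    i+1 must not block; for an N-terminal rule, residue i+1 must be a
    cleavage residue.  The implicit cut at the protein's end is never
    emitted.
    """
    sites = []
    n = len(protein)
    for i in range(1, n):  # cut between protein[i-1] and protein[i]
        if rule.terminus == "C":
            if protein[i - 1] in rule.cleave_residues and protein[i] not in rule.blocked_next:
                sites.append(i)
        else:
            if protein[i] in rule.cleave_residues:
                sites.append(i)
    return sites


def digest(
    protein: str,
    params: DigestParams,
    apply_length_filter: bool = True,
    transcript_id: str | None = None,
) -> list[Peptide]:
    """Digest a protein into position-anchored peptides.

    Fragments between consecutive cut boundaries (including the protein
    termini) carry 0 missed cleavages; every concatenation of up to
    ``max_missed_cleavages + 1`` adjacent fragments is also emitted, with its
    missed-cleavage count.  With ``apply_length_filter``, only peptides
    within [min_len, max_len] are returned.  Output is ordered by (start,
    end); identical sequences at distinct positions are distinct records.
    """
    if not protein:
        return []
    bounds = [0] + cleavage_sites(protein, params.rule) + [len(protein)]
    peptides: list[Peptide] = []
    nfrag = len(bounds) - 1
    for i in range(nfrag):
        for mc in range(params.max_missed_cleavages + 1):
            j = i + mc + 1
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            seq = protein[start:end]
            if apply_length_filter and not (
                params.min_len <= len(seq) <= params.max_len
            ):
                continue
            peptides.append(
                Peptide(
                    sequence=seq,
                    start=start + 1,
                    end=end,
                    missed_cleavages=mc,
                    enzyme=params.enzyme,
                    transcript_id=transcript_id,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def missed_cleavage_distribution(peptides: list[Peptide]) -> dict[int, int]:
    """Count peptides per missed-cleavage value."""
    return dict(sorted(Counter(p.missed_cleavages for p in peptides).items()))


@dataclass
class PeptideIndex:
    """peptide sequence -> set of transcript_ids whose digest contains it."""

    entries: dict[str, set[str]] = field(default_factory=dict)
    scope: set[str] = field(default_factory=set)

    def add(self, sequence: str, transcript_id: str) -> None:
        self.scope.add(transcript_id)
        self.entries.setdefault(sequence, set()).add(transcript_id)

    def transcripts_of(self, sequence: str) -> set[str]:
        return set(self.entries.get(sequence, set()))

    def __len__(self) -> int:
        return len(self.entries)


def digest_transcriptome(
    genes: list[GeneModel],
    genome: Genome,
    params: DigestParams,
    apply_length_filter: bool = True,
) -> tuple[PeptideIndex, dict[str, list[Peptide]]]:
    """Digest every coding transcript of every gene.

    Returns the sequence -> transcript-set index plus the per-transcript
    position-anchored peptide lists.  Non-coding transcripts are indexed in
    scope-free terms: they contribute nothing.
    """
    index = PeptideIndex()
    per_transcript: dict[str, list[Peptide]] = {}
    for gene in genes:
        for t in gene.coding_transcripts():
            protein = translate_cds(spliced_cds_sequence(t, genome)).sequence
            peps = digest(
                protein,
                params,
                apply_length_filter=apply_length_filter,
                transcript_id=t.transcript_id,
            )
            per_transcript[t.transcript_id] = peps
            index.scope.add(t.transcript_id)
            for p in peps:
                index.add(p.sequence, t.transcript_id)
    return index, per_transcript


def peptides_to_table(peptides: list[Peptide]):
    """Peptide list -> DataFrame (transcript_id, peptide, start, end, mc, enzyme)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "transcript_id": [p.transcript_id for p in peptides],
            "peptide": [p.sequence for p in peptides],
            "start": [p.start for p in peptides],
            "end": [p.end for p in peptides],
            "mc": [p.missed_cleavages for p in peptides],
            "enzyme": [p.enzyme for p in peptides],
        }
    )


def peptides_from_table(df) -> list[Peptide]:
    """Inverse of :func:`peptides_to_table`."""
    return [
        Peptide(
            sequence=row.peptide,
            start=int(row.start),
            end=int(row.end),
            missed_cleavages=int(row.mc),
            enzyme=row.enzyme,
            transcript_id=None if row.transcript_id in (None, "") else row.transcript_id,
        )
        for row in df.itertuples()
    ]
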