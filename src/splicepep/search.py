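"""Peptide-centric search: which isoforms encode a query peptide?

The built-in engine is an exact / Hamming-distance window scan over the
translated proteome — no gaps, deterministic, appropriate for short-peptide
lookup.  Non-enzymatic matching is the default (the immunopeptidome case);
an optional enzymatic constraint keeps only matches whose span is a valid
peptide of the named protease's digest (missed cleavages <= 2).
"""

from __future__ import annotations

from dataclasses import dataclass

from .digestion import Peptide, cleavage_sites, protease_rule
from .mapping import map_peptide
from .model import GeneModel, Genome, ProteinRecord

__all__ = ["SearchParams", "SearchHit", "search_peptide", "hits_to_tracks"]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SearchParams:
    max_mismatches: int = 0
    identity_cutoff: float = 1.0
    max_targets: int = 50
    enzymatic_constraint: str | None = None  # None = non-enzymatic

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if not (0.0 <= self.identity_cutoff <= 1.0):
            raise ValueError("identity_cutoff must be in [0, 1]")


@dataclass(frozen=True)
class SearchHit:
    transcript_id: str
    gene_id: str
    match_start: int  # 1-based residue in the target protein
    match_end: int  # inclusive
    identity: float
    mismatches: int


def _valid_enzymatic_span(
    protein: str, start0: int, end0: int, enzyme: str, max_mc: int = 2
) -> bool:
    """Is protein[start0:end0] a peptide of the enzyme's digest (mc <= max_mc)?"""
    sites = set(cleavage_sites(protein, protease_rule(enzyme)))
    boundaries = sites | {0, len(protein)}
    if start0 not in boundaries or end0 not in boundaries:
        return False
    internal = sum(1 for s in sites if start0 < s < end0)
    return internal <= max_mc


def search_peptide(
    query: str,
    proteome: list[ProteinRecord],
    params: SearchParams | None = None,
    gene_ids: dict[str, str] | None = None,
) -> list[SearchHit]:
    """Scan every window of query length in every protein for near matches.

    A window qualifies with <= max_mismatches mismatches and identity
    (matches / length) >= identity_cutoff.  Hits rank by identity
    descending, then transcript_id, then position, truncated to
    ``max_targets``.  Multiple windows per protein are allowed.
    """
    params = params or SearchParams()
    query = query.upper()
    if len(query) < 4:
        raise ValueError("query must be at least 4 residues")
    bad = set(query) - _AA
    if bad:
        raise ValueError(f"invalid residues in query: {sorted(bad)}")
    qlen = len(query)
    hits: list[SearchHit] = []
    for rec in sorted(proteome, key=lambda r: r.transcript_id):
        seq = rec.sequence
        for i in range(len(seq) - qlen + 1):
            window = seq[i : i + qlen]
            mism = sum(1 for a, b in zip(query, window) if a != b)
            if mism > params.max_mismatches:
                continue
            identity = (qlen - mism) / qlen
            if identity < params.identity_cutoff:
                continue
            if params.enzymatic_constraint and not _valid_enzymatic_span(
                seq, i, i + qlen, params.enzymatic_constraint
            ):
                continue
            hits.append(
                SearchHit(
                    transcript_id=rec.transcript_id,
                    gene_id=(gene_ids or {}).get(rec.transcript_id, ""),
                    match_start=i + 1,
                    match_end=i + qlen,
                    identity=identity,
                    mismatches=mism,
                )
            )
    hits.sort(key=lambda h: (-h.identity, h.transcript_id, h.match_start))
    return hits[: params.max_targets]


def hits_to_tracks(
    hits: list[SearchHit],
    genes: list[GeneModel],
    genome: Genome,
) -> dict[str, dict]:
    """Group hits by gene and map match spans to genomic blocks.

    Each gene bundle lists the matched isoforms (with the matched span's
    genomic blocks) plus sibling isoforms lacking the match, flagged as
    unmatched context.
    """
    by_tid = {
        t.transcript_id: (gene, t) for gene in genes for t in gene.transcripts
    }
    bundles: dict[str, dict] = {}
    for hit in hits:
        if hit.transcript_id not in by_tid:
            raise KeyError(f"hit references unknown transcript {hit.transcript_id}")
        gene, t = by_tid[hit.transcript_id]
        bundle = bundles.setdefault(
            gene.gene_id, {"gene_id": gene.gene_id, "matched": [], "context": []}
        )
        pseudo = Peptide(
            sequence="?" * (hit.match_end - hit.match_start + 1),
            start=hit.match_start,
            end=hit.match_end,
            missed_cleavages=0,
            enzyme="query",
            transcript_id=t.transcript_id,
        )
        mp = map_peptide(t, pseudo)
        bundle["matched"].append(
            {
                "transcript_id": t.transcript_id,
                "match_start": hit.match_start,
                "match_end": hit.match_end,
                "identity": hit.identity,
                "blocks": [
                    (b.contig, b.start, b.end, b.strand) for b in mp.blocks
                ],
            }
        )
    for gene_id, bundle in bundles.items():
        gene = next(g for g in genes if g.gene_id == gene_id)
        matched_tids = {m["transcript_id"] for m in bundle["matched"]}
        bundle["context"] = sorted(
            t.transcript_id for t in gene.transcripts
            if t.transcript_id not in matched_tids
        )
    return bundles
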