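"""Isoform-specificity classification, Jaccard similarity, sequence coverage.

A peptide is classified relative to an explicit isoform selection by its
presence pattern: present in exactly one selected transcript -> *unique*;
in all of >= 2 selected transcripts -> *universal*; otherwise *shared*.
Presence is by exact sequence identity anywhere in the digest
(position-agnostic); isoleucine and leucine are distinct letters by default,
with an optional I=L collapse for mass-spectrometric indistinguishability.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .digestion import DigestParams, Peptide, PeptideIndex, digest
from .model import GeneModel, Genome, TranscriptModel, transcript_protein

__all__ = [
    "UNIQUE",
    "SHARED",
    "UNIVERSAL",
    "classify_specificity",
    "jaccard_matrix",
    "sequence_coverage",
    "compare_proteases",
]

UNIQUE = "unique"
SHARED = "shared"
UNIVERSAL = "universal"


def classify_specificity(
    index: PeptideIndex,
    selection: set[str],
    collapse_il: bool = False,
) -> dict[str, str]:
    """Label every peptide present in the selection by its presence pattern.

    Counts are restricted to the selected transcripts; peptides absent from
    all of them are omitted.  A single-transcript selection labels every
    present peptide *unique* (the actionable label for targeted-MS design).
    """
    unknown = selection - index.scope
    if unknown:
        raise ValueError(f"selection contains unknown transcripts: {sorted(unknown)}")
    if not selection:
        raise ValueError("selection must contain at least one transcript")

    entries = index.entries
    if collapse_il:
        collapsed: dict[str, set[str]] = {}
        for seq, tids in entries.items():
            collapsed.setdefault(seq.replace("I", "L"), set()).update(tids)
        entries = collapsed

    labels: dict[str, str] = {}
    n_sel = len(selection)
    for seq, tids in entries.items():
        count = len(tids & selection)
        if count == 0:
            continue
        if count == 1:
            labels[seq] = UNIQUE
        elif count == n_sel:
            labels[seq] = UNIVERSAL
        else:
            labels[seq] = SHARED
    return labels


def jaccard_matrix(peptide_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Symmetric Jaccard similarity matrix between per-transcript peptide sets.

    J(A, B) = |A n B| / |A u B|, defined as 0 when both sets are empty and
    1 on the diagonal.
    """
    if len(peptide_sets) < 2:
        raise ValueError("need >= 2 peptide sets")
    ids = sorted(peptide_sets)
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        mat.loc[a, a] = 1.0
        for b in ids[i + 1 :]:
            union = peptide_sets[a] | peptide_sets[b]
            j = len(peptide_sets[a] & peptide_sets[b]) / len(union) if union else 0.0
            mat.loc[a, b] = j
            mat.loc[b, a] = j
    return mat


def sequence_coverage(peptides: list[Peptide], protein_length: int) -> float:
    """Fraction of protein residues covered by >= 1 peptide.

    Overlapping/adjacent residue spans are merged before counting.
    """
    if protein_length <= 0:
        raise ValueError("protein_length must be positive")
    spans = sorted((p.start, p.end) for p in peptides)
    covered = 0
    cur_start = cur_end = None
    for s, e in spans:
        if not (1 <= s <= e <= protein_length):
            raise ValueError(f"span {s}-{e} outside protein of length {protein_length}")
        if cur_end is None:
            cur_start, cur_end = s, e
        elif s <= cur_end + 1:
            cur_end = max(cur_end, e)
        else:
            covered += cur_end - cur_start + 1
            cur_start, cur_end = s, e
    if cur_end is not None:
        covered += cur_end - cur_start + 1
    return covered / protein_length


def compare_proteases(
    t: TranscriptModel,
    gene: GeneModel,
    genome: Genome,
    enzymes: list[str],
    params_by_enzyme: dict[str, DigestParams] | None = None,
) -> pd.DataFrame:
    """Per-enzyme digest summary for one transcript against its gene's isoforms.

    For each enzyme, all coding isoforms of the gene are digested
    (length-filtered), peptides are classified against the full coding
    selection, and the row reports the transcript's sequence coverage, its
    count of unique-labeled peptides, and its total distinct peptides.
    """
    if t.transcript_id not in {x.transcript_id for x in gene.transcripts}:
        raise ValueError(f"{t.transcript_id} is not a transcript of {gene.gene_id}")
    proteins = {
        x.transcript_id: transcript_protein(x, genome).sequence
        for x in gene.coding_transcripts()
    }
    selection = set(proteins)
    rows = []
    for enzyme in enzymes:
        params = (params_by_enzyme or {}).get(enzyme, DigestParams(enzyme=enzyme))
        if params.enzyme != enzyme:
            params = replace(params, enzyme=enzyme)
        index = PeptideIndex()
        digests: dict[str, list[Peptide]] = {}
        for tid, protein in proteins.items():
            peps = digest(protein, params, apply_length_filter=True, transcript_id=tid)
            digests[tid] = peps
            index.scope.add(tid)
            for p in peps:
                index.add(p.sequence, tid)
        labels = classify_specificity(index, selection)
        own = digests[t.transcript_id]
        own_seqs = {p.sequence for p in own}
        rows.append(
            {
                "enzyme": enzyme,
                "coverage": sequence_coverage(own, len(proteins[t.transcript_id])),
                "unique_peptide_count": sum(
                    1 for s in own_seqs if labels.get(s) == UNIQUE
                ),
                "total_peptide_count": len(own_seqs),
            }
        )
    return pd.DataFrame(rows)
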