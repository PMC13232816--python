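"""Stacked track layout for transcript + peptide plots, and static export.

The layout is a deterministic greedy first-fit: peptides sorted by (outer
genomic span start, span end, sequence) are each placed in the lowest row
where they overlap no prior occupant.  Overlap is judged on the peptide's
outer genomic span so junction peptides occupy a single visual row.

Rendering is static (SVG/PDF via matplotlib); every drawn element also goes
into a companion TSV — the testable surface — including the per-peptide
hover fields (sequence, genomic position, enzyme, specificity).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .mapping import MappedPeptide
from .model import TranscriptModel

__all__ = ["stack_layout", "render_tracks", "DEFAULT_PALETTE"]

DEFAULT_PALETTE = {
    "unique": "#d62728",
    "shared": "#1f77b4",
    "universal": "#7f7f7f",
    "cds": "#2ca02c",
    "exon": "#bbbbbb",
}


def stack_layout(mps: list[MappedPeptide]) -> list[tuple[MappedPeptide, int]]:
    """Assign each mapped peptide to a row; no two row-mates overlap.

    Deterministic: input order does not matter.  Returns (peptide, row)
    pairs in the placement order.
    """
    contigs = {mp.contig for mp in mps}
    if len(contigs) > 1:
        raise ValueError(f"layout requires one contig, got {sorted(contigs)}")
    ordered = sorted(
        mps, key=lambda mp: (*mp.genomic_span, mp.peptide.sequence)
    )
    row_ends: list[int] = []  # max occupied end per row
    placed = []
    for mp in ordered:
        start, end = mp.genomic_span
        for row, occupied_end in enumerate(row_ends):
            if start >= occupied_end:  # half-open spans: abutting is free
                row_ends[row] = end
                placed.append((mp, row))
                break
        else:
            row_ends.append(end)
            placed.append((mp, len(row_ends) - 1))
    return placed


def render_tracks(
    transcripts: list[TranscriptModel],
    layout: list[tuple[MappedPeptide, int]],
    specificity: dict[str, str],
    out_figure: str | Path,
    out_table: str | Path,
    palette: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Draw exon/CDS/peptide tracks and write the companion element table.

    Exons are rectangles at genomic coordinates with CDS regions overlaid as
    narrower rectangles; peptides are colored by specificity class.  The
    returned DataFrame (also written to ``out_table``) lists every drawn
    element with coordinates, row, color class and hover fields.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    palette = palette or DEFAULT_PALETTE
    for mp, _ in layout:
        label = specificity.get(mp.peptide.sequence, "unique")
        if label not in palette:
            raise ValueError(f"unknown specificity label {label!r}")

    rows = []
    n_transcripts = len(transcripts)
    fig_height = 1 + 0.4 * (n_transcripts + max((r for _, r in layout), default=0) + 1)
    fig, ax = plt.subplots(figsize=(10, fig_height))

    for ti, t in enumerate(transcripts):
        y = -(ti + 1)
        ax.plot(
            [t.span.start, t.span.end], [y, y], color="black", lw=0.8, zorder=1
        )
        for e in t.exons:
            ax.add_patch(
                plt.Rectangle(
                    (e.start, y - 0.15), e.width, 0.3, color=palette["exon"]
                )
            )
            rows.append(
                {
                    "element": "exon", "transcript_id": t.transcript_id,
                    "contig": e.contig, "start": e.start, "end": e.end,
                    "row": -1 - ti, "color_class": "exon",
                    "sequence": "", "enzyme": "", "specificity": "",
                }
            )
        for c in t.cds_blocks:
            ax.add_patch(
                plt.Rectangle(
                    (c.start, y - 0.08), c.width, 0.16, color=palette["cds"]
                )
            )
            rows.append(
                {
                    "element": "cds", "transcript_id": t.transcript_id,
                    "contig": c.contig, "start": c.start, "end": c.end,
                    "row": -1 - ti, "color_class": "cds",
                    "sequence": "", "enzyme": "", "specificity": "",
                }
            )

    for mp, row in layout:
        label = specificity.get(mp.peptide.sequence, "unique")
        start, end = mp.genomic_span
        y = row + 1
        for b in mp.blocks:
            ax.add_patch(
                plt.Rectangle(
                    (b.start, y - 0.12), b.width, 0.24, color=palette[label]
                )
            )
        rows.append(
            {
                "element": "peptide",
                "transcript_id": mp.transcript_id,
                "contig": mp.contig,
                "start": start,
                "end": end,
                "row": row,
                "color_class": label,
                "sequence": mp.peptide.sequence,
                "enzyme": mp.peptide.enzyme,
                "specificity": label,
            }
        )

    ax.set_xlabel(transcripts[0].contig if transcripts else "")
    ax.set_yticks([])
    ax.autoscale_view()
    fig.savefig(out_figure, bbox_inches="tight")
    plt.close(fig)

    table = pd.DataFrame(rows)
    table.to_csv(out_table, sep="\t", index=False)
    return table
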