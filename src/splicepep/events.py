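"""Alternative-splicing events: derivation, parsing, translation, detectability.

An event carries the combined genomic range(s) of its alternatively spliced
region, plus the transcript sets that include or exclude that region.
Events come from three sources: pairwise exon-chain comparison of annotated
isoforms, rMATS tables (0-based half-open ``*_0base`` coordinates), or
SplAdder-style tables (1-based inclusive).

Event-level peptide comparison works on unions over the inclusion and
exclusion transcript groups, giving one classification per event.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .mapping import MappedPeptide
from .model import (
    GeneModel,
    Genome,
    GenomicBlock,
    spliced_cds_sequence,
    translate_cds,
)

__all__ = [
    "SpliceEvent",
    "EventPeptideClassification",
    "EventTranslation",
    "derive_events",
    "parse_rmats",
    "write_rmats",
    "parse_spladder",
    "match_event_to_transcripts",
    "overlapping_peptides",
    "classify_event_peptides",
    "translate_event_region",
    "event_detectability",
]

log = logging.getLogger(__name__)

EVENT_TYPES = ("SE", "RI", "MXE", "A3SS", "A5SS")

DETECTABLE = "detectable"
NO_DIFFERENTIAL = "no_differential_peptide"
LENGTH_OUT_OF_RANGE = "length_out_of_range"


@dataclass(frozen=True)
class SpliceEvent:
    event_id: str
    event_type: str
    gene_id: str
    contig: str
    strand: str
    alt_regions: tuple[GenomicBlock, ...]
    inclusion_transcripts: frozenset[str] = frozenset()
    exclusion_transcripts: frozenset[str] = frozenset()
    ambiguous_transcripts: frozenset[str] = frozenset()
    source: str = "annotation"

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not self.alt_regions:
            raise ValueError("alt_regions must be non-empty")
        n = len(self.alt_regions)
        if self.event_type == "MXE" and n != 2:
            raise ValueError("MXE events carry exactly 2 alt regions")
        if self.event_type != "MXE" and n != 1:
            raise ValueError(f"{self.event_type} events carry exactly 1 alt region")
        if self.inclusion_transcripts & self.exclusion_transcripts:
            raise ValueError("inclusion and exclusion sets must be disjoint")

    @property
    def locus(self) -> GenomicBlock:
        """Flank-to-flank span of all alternative regions."""
        return GenomicBlock(
            self.contig,
            min(r.start for r in self.alt_regions),
            max(r.end for r in self.alt_regions),
            self.strand,
        )


@dataclass(frozen=True)
class EventPeptideClassification:
    inclusion_specific: frozenset[str]
    exclusion_specific: frozenset[str]
    common: frozenset[str]


@dataclass(frozen=True)
class EventTranslation:
    """In-frame translation of one alternative region (or a non-coding flag)."""

    region: GenomicBlock
    coding: bool
    sequence: str = ""


# ---------------------------------------------------------------------------
# derivation from annotation


def _chain(t) -> list[GenomicBlock]:
    return list(t.exons)


def _classify_pair(a, b) -> list[tuple[str, tuple[GenomicBlock, ...], str]]:
    """Compare two exon chains; return (type, alt_regions, inclusion_tid).

    Recognized patterns: SE (one chain has one extra internal exon between
    shared flanks), RI (one exon of A spans two exons of B plus the intron,
    outer boundaries shared), MXE (one differing exon each at the same slot,
    mutually exclusive), A5SS/A3SS (one exon boundary differs; named by
    transcription side using strand).  Unrecognized differences yield no
    events.
    """
    ea, eb = _chain(a), _chain(b)
    if ea == eb:
        return []
    out = []
    # SE: one extra exon in the longer chain
    for long_t, short_t in ((a, b), (b, a)):
        el, es = _chain(long_t), _chain(short_t)
        if len(el) != len(es) + 1:
            continue
        for i in range(len(el)):
            if el[:i] + el[i + 1 :] == es and 0 < i < len(el) - 1:
                extra = el[i]
                if el[i - 1].end <= extra.start and extra.end <= el[i + 1].start:
                    out.append(("SE", (extra,), long_t.transcript_id))
        if out:
            return out
    # RI: one exon of the shorter chain spans two exons + intron of the longer
    for ret_t, spl_t in ((a, b), (b, a)):
        er, es = _chain(ret_t), _chain(spl_t)
        if len(es) != len(er) + 1:
            continue
        for i, exon in enumerate(er):
            left, right = es[i], es[i + 1] if i + 1 < len(es) else None
            if right is None:
                continue
            if (
                exon.start == left.start
                and exon.end == right.end
                and er[:i] == es[:i]
                and er[i + 1 :] == es[i + 2 :]
            ):
                intron = GenomicBlock(
                    exon.contig, left.end, right.start, ret_t.strand
                )
                out.append(("RI", (intron,), ret_t.transcript_id))
        if out:
            return out
    if len(ea) == len(eb):
        diffs = [i for i, (x, y) in enumerate(zip(ea, eb)) if x != y]
        if len(diffs) == 1:
            i = diffs[0]
            x, y = ea[i], eb[i]
            # MXE: fully disjoint middle exons between shared flanks
            if (x.end <= y.start or y.end <= x.start) and 0 < i < len(ea) - 1:
                regions = tuple(sorted((x, y), key=lambda r: r.start))
                inclusion = (
                    a.transcript_id if regions[0] == x else b.transcript_id
                )
                return [("MXE", regions, inclusion)]
            # A5SS / A3SS: exactly one boundary differs
            if x.start == y.start and x.end != y.end:
                lo, hi = sorted((x.end, y.end))
                region = GenomicBlock(x.contig, lo, hi, a.strand)
                longer = a if x.end > y.end else b
                etype = "A5SS" if a.strand == "+" else "A3SS"
                return [(etype, (region,), longer.transcript_id)]
            if x.end == y.end and x.start != y.start:
                lo, hi = sorted((x.start, y.start))
                region = GenomicBlock(x.contig, lo, hi, a.strand)
                longer = a if x.start < y.start else b
                etype = "A3SS" if a.strand == "+" else "A5SS"
                return [(etype, (region,), longer.transcript_id)]
    return out


def derive_events(gene: GeneModel) -> list[SpliceEvent]:
    """Derive AS events from pairwise exon-chain comparison of a gene's isoforms.

    Duplicate events (same type + alt regions) are merged, accumulating
    inclusion/exclusion transcript sets.
    """
    merged: dict[tuple, dict] = {}
    for a, b in itertools.combinations(gene.transcripts, 2):
        for etype, regions, inclusion_tid in _classify_pair(a, b):
            key = (etype, regions)
            rec = merged.setdefault(key, {"inc": set(), "exc": set()})
            pair = {a.transcript_id, b.transcript_id}
            rec["inc"].add(inclusion_tid)
            rec["exc"] |= pair - {inclusion_tid}
    out = []
    for n, ((etype, regions), rec) in enumerate(sorted(merged.items()), start=1):
        out.append(
            SpliceEvent(
                event_id=f"{gene.gene_id}.{etype}.{n}",
                event_type=etype,
                gene_id=gene.gene_id,
                contig=gene.contig,
                strand=gene.strand,
                alt_regions=regions,
                inclusion_transcripts=frozenset(rec["inc"]),
                exclusion_transcripts=frozenset(rec["exc"] - rec["inc"]),
                source="annotation",
            )
        )
    return out


# ---------------------------------------------------------------------------
# rMATS / SplAdder parsing

_RMATS_COMMON = ["ID", "GeneID", "chr", "strand"]
_RMATS_COLS = {
    "SE": ["exonStart_0base", "exonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"],
    "RI": ["riExonStart_0base", "riExonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"],
    "MXE": ["1stExonStart_0base", "1stExonEnd", "2ndExonStart_0base",
            "2ndExonEnd", "upstreamES", "upstreamEE", "downstreamES",
            "downstreamEE"],
    "A5SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE",
             "flankingES", "flankingEE"],
    "A3SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE",
             "flankingES", "flankingEE"],
}


def _alt_regions_from_rmats(row, event_type, contig, strand):
    if event_type == "SE":
        return (GenomicBlock(contig, row["exonStart_0base"], row["exonEnd"], strand),)
    if event_type == "RI":
        return (GenomicBlock(contig, row["upstreamEE"], row["downstreamES"], strand),)
    if event_type == "MXE":
        return (
            GenomicBlock(contig, row["1stExonStart_0base"], row["1stExonEnd"], strand),
            GenomicBlock(contig, row["2ndExonStart_0base"], row["2ndExonEnd"], strand),
        )
    # A5SS / A3SS: the differential segment between long and short exon
    if row["longExonStart_0base"] == row["shortES"]:
        return (GenomicBlock(contig, row["shortEE"], row["longExonEnd"], strand),)
    return (GenomicBlock(contig, row["longExonStart_0base"], row["shortES"], strand),)


def parse_rmats(path, event_type: str) -> list[SpliceEvent]:
    """Parse an rMATS JC/JCEC-style table for one event type.

    rMATS ``*_0base``/``*ES`` starts are 0-based, ends exclusive — already
    the internal convention.  Inclusion/exclusion transcript sets are left
    empty for later matching against annotation.
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}")
    df = pd.read_csv(path, sep="\t")
    required = _RMATS_COMMON + _RMATS_COLS[event_type]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"rMATS table {path} lacks required column {col!r}")
    events = []
    for _, row in df.iterrows():
        contig, strand = str(row["chr"]), str(row["strand"])
        events.append(
            SpliceEvent(
                event_id=f"{event_type}_{row['ID']}",
                event_type=event_type,
                gene_id=str(row["GeneID"]),
                contig=contig,
                strand=strand,
                alt_regions=_alt_regions_from_rmats(row, event_type, contig, strand),
                source="rmats",
            )
        )
    return events


def write_rmats(events: list[SpliceEvent], path, event_type: str) -> None:
    """Write events back into the rMATS coordinate dialect (round-trip aid).

    Flanking-exon columns that the event object does not carry are written
    as placeholder coordinates flanking the alternative region.
    """
    rows = []
    for n, e in enumerate(events, start=1):
        if e.event_type != event_type:
            raise ValueError("all events must share the requested type")
        r = {"ID": n, "GeneID": e.gene_id, "chr": e.contig, "strand": e.strand}
        a = e.alt_regions
        if event_type == "SE":
            r.update(
                exonStart_0base=a[0].start, exonEnd=a[0].end,
                upstreamES=max(0, a[0].start - 100), upstreamEE=a[0].start,
                downstreamES=a[0].end, downstreamEE=a[0].end + 100,
            )
        elif event_type == "RI":
            r.update(
                riExonStart_0base=max(0, a[0].start - 100),
                riExonEnd=a[0].end + 100,
                upstreamES=max(0, a[0].start - 100), upstreamEE=a[0].start,
                downstreamES=a[0].end, downstreamEE=a[0].end + 100,
            )
        elif event_type == "MXE":
            r.update(
                **{
                    "1stExonStart_0base": a[0].start, "1stExonEnd": a[0].end,
                    "2ndExonStart_0base": a[1].start, "2ndExonEnd": a[1].end,
                },
                upstreamES=max(0, a[0].start - 100), upstreamEE=a[0].start,
                downstreamES=a[1].end, downstreamEE=a[1].end + 100,
            )
        else:  # A5SS / A3SS: encode the differential segment as long vs short
            r.update(
                longExonStart_0base=max(0, a[0].start - 50),
                longExonEnd=a[0].end,
                shortES=max(0, a[0].start - 50), shortEE=a[0].start,
                flankingES=a[0].end + 50, flankingEE=a[0].end + 150,
            )
        rows.append(r)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_SPLADDER_PREFIX = {
    "exon_skip": "SE",
    "intron_retention": "RI",
    "mutex_exons": "MXE",
    "alt_3prime": "A3SS",
    "alt_5prime": "A5SS",
}

_SPLADDER_COMMON = ["contig", "strand", "event_id", "gene_name"]


def parse_spladder(path) -> list[SpliceEvent]:
    """Parse a SplAdder-style confirmed-events TSV.

    The event type is encoded in the ``event_id`` prefix (``exon_skip_1``,
    ``intron_retention_2``, ...).  Coordinates are 1-based inclusive in the
    ``alt1_start/alt1_end`` (and, for mutually exclusive exons,
    ``alt2_start/alt2_end``) columns and are converted to the internal
    0-based half-open convention.
    """
    df = pd.read_csv(path, sep="\t")
    for col in _SPLADDER_COMMON + ["alt1_start", "alt1_end"]:
        if col not in df.columns:
            raise ValueError(f"SplAdder table {path} lacks required column {col!r}")
    events = []
    for _, row in df.iterrows():
        eid = str(row["event_id"])
        etype = next(
            (t for p, t in _SPLADDER_PREFIX.items() if eid.startswith(p)), None
        )
        if etype is None:
            raise ValueError(f"unrecognized SplAdder event id prefix in {eid!r}")
        contig, strand = str(row["contig"]), str(row["strand"])

        def conv(s, e):
            start, end = int(s) - 1, int(e)
            if start >= end:
                raise ValueError(
                    f"malformed coordinates {s}-{e} in event {eid!r}"
                )
            return GenomicBlock(contig, start, end, strand)

        regions = [conv(row["alt1_start"], row["alt1_end"])]
        if etype == "MXE":
            if "alt2_start" not in row or "alt2_end" not in row:
                raise ValueError(
                    f"MXE event {eid!r} needs alt2_start/alt2_end columns"
                )
            regions.append(conv(row["alt2_start"], row["alt2_end"]))
        events.append(
            SpliceEvent(
                event_id=eid,
                event_type=etype,
                gene_id=str(row["gene_name"]),
                contig=contig,
                strand=strand,
                alt_regions=tuple(regions),
                source="spladder",
            )
        )
    return events


# ---------------------------------------------------------------------------
# matching, intersection, classification


def _exonic_cover(t, region: GenomicBlock) -> int:
    """Number of region bases covered by the transcript's exons."""
    return sum(
        max(0, min(e.end, region.end) - max(e.start, region.start))
        for e in t.exons
    )


def match_event_to_transcripts(e: SpliceEvent, gene: GeneModel) -> SpliceEvent:
    """Fill an event's inclusion/exclusion sets from a gene's isoforms.

    Inclusion transcripts fully cover the alternative region(s) with exonic
    bases; exclusion transcripts overlap the event locus but are exonically
    disjoint from them; partial coverers are reported as ambiguous.  For
    mutually exclusive exons, inclusion covers the first region and avoids
    the second, and vice versa for exclusion.
    """
    if gene.contig != e.contig or gene.strand != e.strand:
        raise ValueError(
            f"event {e.event_id} on {e.contig}({e.strand}) does not match "
            f"gene {gene.gene_id} on {gene.contig}({gene.strand})"
        )
    inc, exc, amb = set(), set(), set()
    locus = e.locus
    for t in gene.transcripts:
        if not (t.span.start < locus.end and locus.start < t.span.end):
            continue
        covers = [_exonic_cover(t, r) for r in e.alt_regions]
        full = [c == r.width for c, r in zip(covers, e.alt_regions)]
        none = [c == 0 for c in covers]
        if e.event_type == "MXE":
            if full[0] and none[1]:
                inc.add(t.transcript_id)
            elif full[1] and none[0]:
                exc.add(t.transcript_id)
            elif all(none):
                exc.add(t.transcript_id)
            else:
                amb.add(t.transcript_id)
        else:
            if all(full):
                inc.add(t.transcript_id)
            elif all(none):
                exc.add(t.transcript_id)
            else:
                amb.add(t.transcript_id)
    if not inc and not exc:
        log.warning(
            "event %s: no transcript of %s qualifies as inclusion or exclusion",
            e.event_id,
            gene.gene_id,
        )
    return replace(
        e,
        inclusion_transcripts=frozenset(inc),
        exclusion_transcripts=frozenset(exc),
        ambiguous_transcripts=frozenset(amb),
    )


def overlapping_peptides(
    e: SpliceEvent, mps: list[MappedPeptide]
) -> list[MappedPeptide]:
    """Peptides with >= 1 nt of genomic overlap with any alternative region."""
    out = []
    for mp in mps:
        if any(
            blk.contig == r.contig and blk.start < r.end and r.start < blk.end
            for blk in mp.blocks
            for r in e.alt_regions
        ):
            out.append(mp)
    return out


def classify_event_peptides(
    e: SpliceEvent, digests: dict[str, set[str]]
) -> EventPeptideClassification:
    """Set-compare peptide unions of inclusion vs exclusion transcripts."""
    if not e.inclusion_transcripts or not e.exclusion_transcripts:
        raise ValueError(
            f"event {e.event_id} has an empty inclusion or exclusion set; "
            "run match_event_to_transcripts first"
        )
    inc: set[str] = set()
    for tid in e.inclusion_transcripts:
        inc |= digests.get(tid, set())
    exc: set[str] = set()
    for tid in e.exclusion_transcripts:
        exc |= digests.get(tid, set())
    return EventPeptideClassification(
        inclusion_specific=frozenset(inc - exc),
        exclusion_specific=frozenset(exc - inc),
        common=frozenset(inc & exc),
    )


def translate_event_region(
    e: SpliceEvent, gene: GeneModel, genome: Genome
) -> list[EventTranslation]:
    """In-frame translation of each alternative region.

    The reading frame comes from an inclusion transcript whose CDS overlaps
    the region: the region's bases are located on the cumulative spliced-CDS
    axis, trimmed to complete codons (leading bases before the next codon
    start and any trailing partial codon dropped) and translated.  A region
    outside every inclusion transcript's CDS is reported non-coding.
    """
    results = []
    inclusion = [
        gene.get_transcript(tid)
        for tid in sorted(e.inclusion_transcripts)
        if gene.get_transcript(tid).is_coding
    ]
    # prefer inclusion isoforms' frames, fall back to any coding isoform
    # (the second region of a mutually-exclusive pair sits in the CDS of the
    # other isoform)
    candidates = inclusion + [
        t for t in gene.coding_transcripts() if t not in inclusion
    ]
    for region in e.alt_regions:
        translated = None
        for t in candidates:
            positions = _region_cds_positions(t, region)
            if not positions:
                continue
            lo, hi = min(positions), max(positions)  # 1-based cumulative CDS nt
            if (lo - 1) % 3:
                lo += 3 - (lo - 1) % 3
            hi -= hi % 3
            if hi - lo + 1 < 3:
                translated = EventTranslation(region, coding=True, sequence="")
                break
            cds = spliced_cds_sequence(t, genome)
            aa = translate_cds(cds[lo - 1 : hi]).sequence
            translated = EventTranslation(region, coding=True, sequence=aa)
            break
        results.append(
            translated
            if translated is not None
            else EventTranslation(region, coding=False)
        )
    return results


def _region_cds_positions(t, region: GenomicBlock) -> list[int]:
    """1-based cumulative spliced-CDS positions covered by a genomic region."""
    positions = []
    cum = 0
    for b in t.blocks_in_transcription_order("cds"):
        lo = max(b.start, region.start)
        hi = min(b.end, region.end)
        if lo < hi:
            for g in range(lo, hi):
                if t.strand == "+":
                    offset = g - b.start
                else:
                    offset = b.end - 1 - g
                pos0 = cum + offset - t.frame_of_first_cds_codon
                if pos0 >= 0:
                    positions.append(pos0 + 1)
        cum += b.width
    return positions


def event_detectability(
    e: SpliceEvent,
    filtered_digests: dict[str, set[str]],
    unfiltered_digests: dict[str, set[str]],
) -> str:
    """Three-way verdict on whether an event leaves an MS-visible trace.

    ``detectable``: length-filtered digests yield differential peptides.
    ``no_differential_peptide``: even unfiltered digests are identical
    between inclusion and exclusion forms (non-coding event or silent at
    the peptide level).  ``length_out_of_range``: differential peptides
    exist but all fall outside the length window.
    """
    if not e.inclusion_transcripts or not e.exclusion_transcripts:
        return NO_DIFFERENTIAL
    filt = classify_event_peptides(e, filtered_digests)
    if filt.inclusion_specific or filt.exclusion_specific:
        return DETECTABLE
    raw = classify_event_peptides(e, unfiltered_digests)
    if raw.inclusion_specific or raw.exclusion_specific:
        return LENGTH_OUT_OF_RANGE
    return NO_DIFFERENTIAL
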