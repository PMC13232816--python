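import pandas as pd
import pytest

from splicepep import (
    GenomicBlock,
    SpliceEvent,
    TranscriptModel,
    classify_event_peptides,
    derive_events,
    event_detectability,
    match_event_to_transcripts,
    overlapping_peptides,
    parse_rmats,
    parse_spladder,
    translate_event_region,
)
from splicepep.events import write_rmats


class TestDeriveEvents:
    def test_each_planted_gene_yields_its_event(self, fx):
        for gene in fx.genes:
            events = derive_events(gene)
            planted = fx.events[gene.gene_id]
            assert len(events) == 1
            e = events[0]
            assert e.event_type == planted.event_type
            assert e.alt_regions == planted.alt_regions
            assert e.inclusion_transcripts == {planted.inclusion}
            assert e.exclusion_transcripts == {planted.exclusion}

    def test_identical_chains_yield_nothing(self, fx):
        gene = fx.gene("GSE")
        t = gene.get_transcript("T_SE_INC")
        clone = TranscriptModel(
            transcript_id="T_CLONE", gene_id=t.gene_id, gene_name=t.gene_name,
            strand=t.strand, exons=list(t.exons), cds_blocks=list(t.cds_blocks),
        )
        from splicepep import GeneModel

        pair = GeneModel(gene_id=t.gene_id, gene_name=t.gene_name,
                         transcripts=[t, clone])
        assert derive_events(pair) == []

    def test_retained_intron_alt_region_is_the_intron(self, fx):
        gene = fx.gene("GRI")
        (e,) = derive_events(gene)
        spl = gene.get_transcript("T_RI_SPL")
        intron = GenomicBlock(
            gene.contig, spl.exons[0].end, spl.exons[1].start, gene.strand
        )
        assert e.alt_regions == (intron,)


class TestRmatsParsing:
    def _write(self, tmp_path, columns, rows):
        path = tmp_path / "events.txt"
        pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
        return path

    def test_se_alt_region(self, tmp_path):
        path = self._write(
            tmp_path,
            ["ID", "GeneID", "chr", "strand", "exonStart_0base", "exonEnd",
             "upstreamES", "upstreamEE", "downstreamES", "downstreamEE"],
            [[1, "G", "chrT", "+", 200, 230, 100, 150, 300, 350]],
        )
        (e,) = parse_rmats(path, "SE")
        assert e.alt_regions == (GenomicBlock("chrT", 200, 230, "+"),)

    def test_a5ss_differential_segment(self, tmp_path):
        path = self._write(
            tmp_path,
            ["ID", "GeneID", "chr", "strand", "longExonStart_0base",
             "longExonEnd", "shortES", "shortEE", "flankingES", "flankingEE"],
            [[1, "G", "chrT", "+", 200, 330, 200, 310, 400, 450]],
        )
        (e,) = parse_rmats(path, "A5SS")
        assert e.alt_regions == (GenomicBlock("chrT", 310, 330, "+"),)

    def test_ri_intron_between_flanks(self, tmp_path):
        path = self._write(
            tmp_path,
            ["ID", "GeneID", "chr", "strand", "riExonStart_0base", "riExonEnd",
             "upstreamES", "upstreamEE", "downstreamES", "downstreamEE"],
            [[1, "G", "chrT", "+", 100, 350, 100, 150, 300, 350]],
        )
        (e,) = parse_rmats(path, "RI")
        assert e.alt_regions == (GenomicBlock("chrT", 150, 300, "+"),)

    def test_mxe_two_regions(self, tmp_path):
        path = self._write(
            tmp_path,
            ["ID", "GeneID", "chr", "strand", "1stExonStart_0base", "1stExonEnd",
             "2ndExonStart_0base", "2ndExonEnd", "upstreamES", "upstreamEE",
             "downstreamES", "downstreamEE"],
            [[1, "G", "chrT", "+", 200, 230, 260, 290, 100, 150, 300, 350]],
        )
        (e,) = parse_rmats(path, "MXE")
        assert e.alt_regions == (
            GenomicBlock("chrT", 200, 230, "+"),
            GenomicBlock("chrT", 260, 290, "+"),
        )

    def test_missing_column_is_error(self, tmp_path):
        path = self._write(
            tmp_path,
            ["ID", "GeneID", "strand", "exonStart_0base", "exonEnd",
             "upstreamES", "upstreamEE", "downstreamES", "downstreamEE"],
            [[1, "G", "+", 200, 230, 100, 150, 300, 350]],
        )
        with pytest.raises(ValueError, match="chr"):
            parse_rmats(path, "SE")

    def test_unknown_event_type_is_error(self, tmp_path):
        with pytest.raises(ValueError):
            parse_rmats(tmp_path / "x.txt", "AFE")

    @pytest.mark.parametrize("etype", ["SE", "RI", "MXE", "A3SS", "A5SS"])
    def test_write_parse_round_trip(self, fx, tmp_path, etype):
        gene_id = {v.event_type: k for k, v in fx.events.items()}[etype]
        events = derive_events(fx.gene(gene_id))
        path = tmp_path / f"{etype}.txt"
        write_rmats(events, path, etype)
        parsed = parse_rmats(path, etype)
        assert [e.alt_regions for e in parsed] == [e.alt_regions for e in events]
        assert [e.contig for e in parsed] == [e.contig for e in events]
        assert [e.strand for e in parsed] == [e.strand for e in events]


class TestSpladderParsing:
    def _write(self, tmp_path, rows, extra_cols=()):
        cols = ["contig", "strand", "event_id", "gene_name",
                "alt1_start", "alt1_end", *extra_cols]
        path = tmp_path / "spladder.txt"
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
        return path

    def test_exon_skip_prefix_maps_to_se(self, tmp_path):
        path = self._write(tmp_path, [["chrT", "+", "exon_skip_1", "G", 201, 230]])
        (e,) = parse_spladder(path)
        assert e.event_type == "SE"
        assert e.alt_regions == (GenomicBlock("chrT", 200, 230, "+"),)

    def test_intron_retention_prefix(self, tmp_path):
        path = self._write(
            tmp_path, [["chrT", "-", "intron_retention_2", "G", 151, 300]]
        )
        (e,) = parse_spladder(path)
        assert e.event_type == "RI"

    def test_unknown_prefix_is_error(self, tmp_path):
        path = self._write(tmp_path, [["chrT", "+", "weird_event_1", "G", 1, 10]])
        with pytest.raises(ValueError, match="prefix"):
            parse_spladder(path)

    def test_malformed_coordinates_are_error(self, tmp_path):
        path = self._write(tmp_path, [["chrT", "+", "exon_skip_1", "G", 231, 230]])
        with pytest.raises(ValueError, match="malformed"):
            parse_spladder(path)


class TestMatching:
    def test_fixture_se_event_matches_planted_isoforms(self, fx):
        gene = fx.gene("GSE")
        planted = fx.events["GSE"]
        e = SpliceEvent(
            event_id="x", event_type="SE", gene_id="GSE", contig=gene.contig,
            strand=gene.strand, alt_regions=planted.alt_regions, source="rmats",
        )
        m = match_event_to_transcripts(e, gene)
        assert m.inclusion_transcripts == {"T_SE_INC"}
        assert m.exclusion_transcripts == {"T_SE_EXC"}

    def test_wrong_contig_is_error(self, fx):
        e = SpliceEvent(
            event_id="x", event_type="SE", gene_id="GSE", contig="chrOther",
            strand="+", alt_regions=(GenomicBlock("chrOther", 10, 20, "+"),),
        )
        with pytest.raises(ValueError):
            match_event_to_transcripts(e, fx.gene("GSE"))

    def test_partial_coverage_is_ambiguous(self, fx):
        gene = fx.gene("GSE")
        cassette = fx.events["GSE"].alt_regions[0]
        half = GenomicBlock(
            cassette.contig, cassette.start,
            cassette.start + cassette.width // 2, cassette.strand,
        )
        t = gene.get_transcript("T_SE_EXC")
        partial = TranscriptModel(
            transcript_id="T_PART", gene_id=gene.gene_id, gene_name=gene.gene_name,
            strand=gene.strand, exons=[t.exons[0], half, t.exons[1]],
        )
        from splicepep import GeneModel

        widened = GeneModel(
            gene_id=gene.gene_id, gene_name=gene.gene_name,
            transcripts=[*gene.transcripts, partial],
        )
        e = SpliceEvent(
            event_id="x", event_type="SE", gene_id="GSE", contig=gene.contig,
            strand=gene.strand, alt_regions=(cassette,),
        )
        m = match_event_to_transcripts(e, widened)
        assert "T_PART" in m.ambiguous_transcripts
        assert "T_PART" not in m.inclusion_transcripts | m.exclusion_transcripts


class TestOverlappingPeptides:
    BLOCKS = [(106, 110), (200, 205)]

    def _mp(self):
        from splicepep import MappedPeptide, Peptide

        p = Peptide(sequence="AAA", start=1, end=3, missed_cleavages=0, enzyme="trypsin")
        return MappedPeptide(
            peptide=p, transcript_id="T",
            blocks=tuple(GenomicBlock("c", s, e, "+") for s, e in self.BLOCKS),
        )

    def _event(self, start, end):
        return SpliceEvent(
            event_id="x", event_type="SE", gene_id="G", contig="c", strand="+",
            alt_regions=(GenomicBlock("c", start, end, "+"),),
        )

    def test_single_nucleotide_overlap_qualifies(self):
        assert overlapping_peptides(self._event(204, 260), [self._mp()])

    def test_half_open_abutment_does_not_qualify(self):
        assert not overlapping_peptides(self._event(205, 260), [self._mp()])

    def test_containing_region_qualifies(self):
        assert overlapping_peptides(self._event(100, 300), [self._mp()])


class TestClassifyEventPeptides:
    def test_planted_cassette_peptides(self, fx, tryptic_digests):
        filt, _ = tryptic_digests
        gene = fx.gene("GSE")
        (e,) = derive_events(gene)
        cls = classify_event_peptides(e, filt)
        assert fx.planted["cassette_peptide"] in cls.inclusion_specific
        assert fx.planted["exclusion_junction_peptide"] in cls.exclusion_specific

    def test_identical_digests_all_common(self, fx, tryptic_digests):
        filt, _ = tryptic_digests
        (e,) = derive_events(fx.gene("GU3"))
        cls = classify_event_peptides(e, filt)
        assert not cls.inclusion_specific and not cls.exclusion_specific
        assert cls.common == frozenset(filt["T_U3_INC"])

    def test_set_identities(self, fx, tryptic_digests):
        filt, _ = tryptic_digests
        for gene in fx.genes:
            (e,) = derive_events(gene)
            cls = classify_event_peptides(e, filt)
            inc_union = set().union(
                *(filt[t] for t in e.inclusion_transcripts)
            )
            assert len(cls.inclusion_specific) + len(cls.common) == len(inc_union)
            assert not cls.inclusion_specific & cls.exclusion_specific

    def test_empty_sets_are_error(self):
        e = SpliceEvent(
            event_id="x", event_type="SE", gene_id="G", contig="c", strand="+",
            alt_regions=(GenomicBlock("c", 0, 10, "+"),),
        )
        with pytest.raises(ValueError, match="match_event_to_transcripts"):
            classify_event_peptides(e, {})


class TestTranslateEventRegion:
    def test_cassette_translates_to_planted_residues(self, fx, proteins):
        gene = fx.gene("GSE")
        (e,) = derive_events(gene)
        (tr,) = translate_event_region(e, gene, fx.genome)
        assert tr.coding
        assert tr.sequence in proteins["T_SE_INC"]
        assert tr.sequence == "LNDAGVTR"

    def test_utr_region_is_non_coding(self, fx):
        gene = fx.gene("GU3")
        (e,) = derive_events(gene)
        (tr,) = translate_event_region(e, gene, fx.genome)
        assert not tr.coding

    def test_partial_codon_trimmed(self, fx):
        gene = fx.gene("GSE")
        cassette = fx.events["GSE"].alt_regions[0]
        sub = GenomicBlock(
            cassette.contig, cassette.start, cassette.start + 10, cassette.strand
        )
        e = SpliceEvent(
            event_id="x", event_type="SE", gene_id="GSE", contig=gene.contig,
            strand=gene.strand, alt_regions=(sub,),
            inclusion_transcripts=frozenset({"T_SE_INC"}),
            exclusion_transcripts=frozenset({"T_SE_EXC"}),
        )
        (tr,) = translate_event_region(e, gene, fx.genome)
        assert len(tr.sequence) == 3  # 10 nt codon-aligned -> 3 aa, 1 nt dropped
        assert tr.sequence == "LND"


class TestDetectability:
    def test_trichotomy_on_planted_fixtures(self, fx, tryptic_digests):
        filt, raw = tryptic_digests
        for gene in fx.genes:
            (e,) = derive_events(gene)
            verdict = event_detectability(e, filt, raw)
            assert verdict == fx.events[gene.gene_id].expected_verdict

    def test_relaxed_length_window_flips_only_length_cases(self, fx, tryptic_digests):
        _, raw = tryptic_digests
        for gene in fx.genes:
            (e,) = derive_events(gene)
            before = event_detectability(
                e, *_filtered_and_raw(fx, gene)
            )
            relaxed = event_detectability(e, raw, raw)  # window [1, inf)
            if before == "length_out_of_range":
                assert relaxed == "detectable"
            else:
                assert relaxed == before

    def test_verdicts_partition_event_set(self, fx, tryptic_digests):
        filt, raw = tryptic_digests
        verdicts = [
            event_detectability(derive_events(g)[0], filt, raw) for g in fx.genes
        ]
        assert set(verdicts) <= {
            "detectable", "no_differential_peptide", "length_out_of_range"
        }
        assert len(verdicts) == len(fx.genes)


def _filtered_and_raw(fx, gene):
    from splicepep import DigestParams, digest_transcriptome

    params = DigestParams("trypsin", 0)
    _, filt = digest_transcriptome([gene], fx.genome, params)
    _, raw = digest_transcriptome([gene], fx.genome, params, apply_length_filter=False)
    return (
        {tid: {p.sequence for p in ps} for tid, ps in filt.items()},
        {tid: {p.sequence for p in ps} for tid, ps in raw.items()},
    )

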