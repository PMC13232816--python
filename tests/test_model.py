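import textwrap

import pytest

from splicepep import (
    GeneModel,
    Genome,
    GenomicBlock,
    TranscriptModel,
    read_annotation,
    read_genome,
    spliced_cds_sequence,
    transcript_protein,
    translate_cds,
    write_annotation_gtf,
)


class TestReadGenome:
    def test_single_record_read_back(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chrT\nACGT\n")
        g = read_genome(p)
        assert g.contigs == {"chrT": "ACGT"}

    def test_header_token_and_uppercase(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chrT description here\nacgt\n")
        g = read_genome(p)
        assert g.contigs == {"chrT": "ACGT"}

    def test_duplicate_contig_is_error(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c\nAC\n>c\nGT\n")
        with pytest.raises(ValueError, match="c"):
            read_genome(p)

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            read_genome(p)

    def test_fetch_returns_exact_interval(self):
        g = Genome(contigs={"c": "ACGTACGT"})
        assert g.fetch("c", 2, 6) == "GTAC"
        assert len(g.fetch("c", 0, 5)) == 5


class TestTranslate:
    @pytest.mark.parametrize(
        "cds,protein",
        [("ATGAAATAA", "MK"), ("ATG", "M"), ("ATGGAAGAT", "MED")],
    )
    def test_standard_code_and_terminal_stop_dropped(self, cds, protein):
        assert translate_cds(cds).sequence == protein

    def test_internal_stop_truncates_with_flag(self):
        res = translate_cds("ATGTAAAAA")
        assert res.sequence == "M"
        assert res.truncated_at_internal_stop

    def test_n_codon_gives_x(self):
        assert translate_cds("ATGANA").sequence == "MX"

    def test_non_acgtn_is_error(self):
        with pytest.raises(ValueError):
            translate_cds("ATGRRR")

    def test_trailing_leftover_nt_warns(self):
        with pytest.warns(UserWarning):
            res = translate_cds("ATGAAAG")
        assert res.sequence == "MK"
        assert res.leftover_nt == 1


def _plus_transcript(genome_seq, cds_blocks, frame=0, exons=None):
    genome = Genome(contigs={"c": genome_seq})
    blocks = [GenomicBlock("c", s, e, "+") for s, e in cds_blocks]
    exon_blocks = (
        [GenomicBlock("c", s, e, "+") for s, e in exons] if exons else blocks
    )
    t = TranscriptModel(
        transcript_id="T", gene_id="G", gene_name="G", strand="+",
        exons=exon_blocks, cds_blocks=blocks, frame_of_first_cds_codon=frame,
    )
    return t, genome


class TestSplicedCds:
    def test_plus_strand_identity(self):
        seq = "x" * 100 + "ATGAAATAA" + "x" * 20
        t, g = _plus_transcript(seq.replace("x", "C"), [(100, 109)])
        assert spliced_cds_sequence(t, g) == "ATGAAATAA"

    def test_minus_strand_reverse_complement(self):
        # plus-strand genome segment TTTCAT reverse-complements to ATGAAA
        seq = "C" * 100 + "TTTCAT" + "C" * 20
        genome = Genome(contigs={"c": seq})
        t = TranscriptModel(
            transcript_id="T", gene_id="G", gene_name="G", strand="-",
            exons=[GenomicBlock("c", 100, 106, "-")],
            cds_blocks=[GenomicBlock("c", 100, 106, "-")],
        )
        assert spliced_cds_sequence(t, genome) == "ATGAAA"

    def test_two_block_concatenation(self):
        seq = list("C" * 300)
        seg1, seg2 = "ATGAAACCCG", "GGTTTAAAGGG"
        seq[100:110] = seg1
        seq[200:211] = seg2
        t, g = _plus_transcript("".join(seq), [(100, 110), (200, 211)])
        assert spliced_cds_sequence(t, g) == seg1 + seg2

    def test_frame_trim(self):
        seq = "C" * 100 + "GATGAAATAA" + "C" * 20
        t, g = _plus_transcript(seq, [(100, 110)], frame=1)
        assert spliced_cds_sequence(t, g) == "ATGAAATAA"

    def test_too_short_after_trim_is_error(self):
        seq = "C" * 200
        t, g = _plus_transcript(seq, [(100, 103)], frame=1)
        with pytest.raises(ValueError):
            spliced_cds_sequence(t, g)


class TestAnnotationIO:
    def test_gtf_coordinates_become_half_open(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            textwrap.dedent(
                """\
                chrT\tsrc\texon\t101\t130\t.\t+\t.\tgene_id "G"; transcript_id "T";
                """
            )
        )
        genes = read_annotation(gtf)
        assert genes[0].transcripts[0].exons[0] == GenomicBlock("chrT", 100, 130, "+")

    def test_exon_only_transcript_flagged_non_coding(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chrT\tsrc\texon\t1\t30\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
        )
        t = read_annotation(gtf)[0].transcripts[0]
        assert not t.is_coding

    def test_cds_outside_exon_is_error(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chrT\tsrc\texon\t1\t30\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
            'chrT\tsrc\tCDS\t50\t70\t.\t+\t0\tgene_id "G"; transcript_id "T";\n'
        )
        with pytest.raises(ValueError):
            read_annotation(gtf)

    def test_missing_transcript_id_is_error(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text('chrT\tsrc\texon\t1\t30\t.\t+\t.\tgene_id "G";\n')
        with pytest.raises(ValueError, match="transcript_id"):
            read_annotation(gtf)

    def test_fixture_round_trip_is_identity(self, fx, tmp_path):
        gtf = tmp_path / "fx.gtf"
        write_annotation_gtf(fx.genes, gtf)
        assert read_annotation(gtf) == sorted(fx.genes, key=lambda g: g.gene_id)


class TestModelInvariants:
    def test_protein_length_matches_cds_length(self, fx):
        for gene in fx.genes:
            for t in gene.coding_transcripts():
                cds = spliced_cds_sequence(t, fx.genome)
                protein = transcript_protein(t, fx.genome).sequence
                assert len(protein) == len(cds) // 3 - 1  # fixture CDS end in stop

    def test_gene_requires_transcripts(self):
        with pytest.raises(ValueError):
            GeneModel(gene_id="G", gene_name="G", transcripts=[])

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TranscriptModel(
                transcript_id="T", gene_id="G", gene_name="G", strand="+",
                exons=[GenomicBlock("c", 0, 10, "+"), GenomicBlock("c", 5, 15, "+")],
            )
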