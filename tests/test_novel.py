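import random

import pytest

from oracles import brute_force_orf
from splicepep import (
    DigestParams,
    map_peptide,
    novel_specific_peptides,
    place_transcript,
    predict_orf,
    similar_reference_isoforms,
    spliced_cds_sequence,
    translate_cds,
)
from splicepep.novel import _interval_jaccard


class TestPredictOrf:
    def test_worked_example(self):
        orf = predict_orf("GGATGAAATTTTAGCC", min_codons=3)
        assert (orf.start_nt, orf.end_nt, orf.protein, orf.complete) == (3, 14, "MKF", True)

    def test_tie_broken_five_prime_most(self):
        # two complete ORFs of equal protein length in different frames
        seq = "ATGAAATAAC" + "ATGCCCTAA"
        orf = predict_orf(seq, min_codons=2)
        assert orf.start_nt == 1

    def test_no_atg_gives_none(self):
        assert predict_orf("CCCCCC", min_codons=1) is None

    def test_incomplete_orf_flagged(self):
        orf = predict_orf("CCATGAAAGAAGAA", min_codons=2)
        assert not orf.complete
        assert orf.protein.startswith("MKE")

    def test_fixture_cdna_orf_equals_annotated_cds(self, fx, transcripts_by_id):
        t = transcripts_by_id["T_SE_INC"]
        cdna = t.spliced_exon_sequence(fx.genome)
        orf = predict_orf(cdna)
        assert orf.complete
        assert orf.protein == translate_cds(spliced_cds_sequence(t, fx.genome)).sequence


def test_orf_prediction_matches_brute_force_enumerator():
    rng = random.Random(424242)
    for _ in range(200):
        n = rng.randint(90, 400)
        seq = "".join(rng.choice("ACGT") for _ in range(n))
        min_codons = rng.choice([2, 5, 10])
        got = predict_orf(seq, min_codons=min_codons)
        expected = brute_force_orf(seq, min_codons)
        if expected is None:
            assert got is None
        else:
            assert (got.start_nt, got.end_nt, got.protein, got.complete) == expected


class TestPlaceTranscript:
    def test_planted_structure_placement(self, fx):
        nt = place_transcript(
            fx.planted["novel_cdna"], fx.genes, fx.genome,
            structure=fx.planted["novel_exon_chain"],
        )
        assert nt.provenance == "user_gtf"
        assert fx.planted["novel_exon"] in nt.model.exons
        assert nt.orf.complete

    def test_exact_match_recovers_annotated_model(self, fx, transcripts_by_id):
        t = transcripts_by_id["T_SE_INC"]
        cdna = t.spliced_exon_sequence(fx.genome)
        nt = place_transcript(cdna, fx.genes, fx.genome)
        assert nt.provenance == "exact_match"
        assert nt.model.exons == t.exons
        assert nt.model.cds_blocks == t.cds_blocks

    def test_structure_sequence_mismatch_is_error(self, fx, transcripts_by_id):
        t = transcripts_by_id["T_SE_INC"]
        cdna = t.spliced_exon_sequence(fx.genome)
        wrong = "T" + cdna[1:]
        if wrong == cdna:
            wrong = "A" + cdna[1:]
        with pytest.raises(ValueError, match="mismatch"):
            place_transcript(wrong, fx.genes, fx.genome, structure=list(t.exons))

    def test_unplaceable_sequence_returns_none(self, fx):
        assert place_transcript("ATGAAA" * 30, fx.genes, fx.genome) is None

    def test_projection_consistency(self, fx):
        nt = place_transcript(
            fx.planted["novel_cdna"], fx.genes, fx.genome,
            structure=fx.planted["novel_exon_chain"],
        )
        recovered = translate_cds(
            spliced_cds_sequence(nt.model, fx.genome)
        ).sequence
        assert recovered == nt.orf.protein


class TestSimilarReferences:
    def _novel(self, fx):
        return place_transcript(
            fx.planted["novel_cdna"], fx.genes, fx.genome,
            structure=fx.planted["novel_exon_chain"],
        )

    def test_closest_reference_ranked_first(self, fx):
        refs = similar_reference_isoforms(self._novel(fx), fx.genes, k=5)
        assert refs[0].transcript_id == "T_SE_INC"

    def test_k_zero_gives_empty(self, fx):
        assert similar_reference_isoforms(self._novel(fx), fx.genes, k=0) == []

    def test_identical_structure_has_similarity_one(self, fx, transcripts_by_id):
        t = transcripts_by_id["T_SE_INC"]
        assert _interval_jaccard(list(t.exons), list(t.exons)) == 1.0


class TestNovelSpecificPeptides:
    def test_planted_peptide_recovered_and_maps_into_novel_exon(self, fx):
        nt = place_transcript(
            fx.planted["novel_cdna"], fx.genes, fx.genome,
            structure=fx.planted["novel_exon_chain"],
        )
        refs = similar_reference_isoforms(nt, fx.genes, k=5)
        peps = novel_specific_peptides(nt, refs, fx.genome, DigestParams("trypsin", 0))
        seqs = {p.sequence for p in peps}
        assert fx.planted["novel_peptide"] in seqs
        target = next(p for p in peps if p.sequence == fx.planted["novel_peptide"])
        mp = map_peptide(nt.model, target)
        exon = fx.planted["novel_exon"]
        for b in mp.blocks:
            assert exon.start <= b.start and b.end <= exon.end

    def test_novel_identical_to_reference_has_no_unique_peptides(
        self, fx, transcripts_by_id
    ):
        t = transcripts_by_id["T_SE_INC"]
        cdna = t.spliced_exon_sequence(fx.genome)
        nt = place_transcript(cdna, fx.genes, fx.genome, transcript_id="NOVEL_X")
        refs = similar_reference_isoforms(nt, fx.genes, k=5)
        assert novel_specific_peptides(nt, refs, fx.genome, DigestParams()) == []

    def test_returned_peptides_absent_from_all_references(self, fx):
        nt = place_transcript(
            fx.planted["novel_cdna"], fx.genes, fx.genome,
            structure=fx.planted["novel_exon_chain"],
        )
        refs = similar_reference_isoforms(nt, fx.genes, k=5)
        peps = novel_specific_peptides(nt, refs, fx.genome, DigestParams())
        from splicepep import DigestParams as DP
        from splicepep import digest, transcript_protein

        ref_seqs = set()
        for r in refs:
            protein = transcript_protein(r, fx.genome).sequence
            ref_seqs |= {
                p.sequence for p in digest(protein, DP(), apply_length_filter=False)
            }
        for p in peps:
            assert p.sequence not in ref_seqs
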