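import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from splicepep import (
    DigestParams,
    MappedPeptide,
    Peptide,
    digest_transcriptome,
    generate_fixture,
    transcript_protein,
)
from splicepep.model import GenomicBlock


@pytest.fixture(scope="session")
def fx():
    """The synthetic genome + annotation with planted ground truth."""
    return generate_fixture(seed=1)


@pytest.fixture(scope="session")
def proteins(fx):
    """transcript_id -> protein sequence for every coding fixture transcript."""
    return {
        t.transcript_id: transcript_protein(t, fx.genome).sequence
        for g in fx.genes
        for t in g.coding_transcripts()
    }


@pytest.fixture(scope="session")
def transcripts_by_id(fx):
    return {t.transcript_id: t for g in fx.genes for t in g.transcripts}


@pytest.fixture(scope="session")
def tryptic_digests(fx):
    """(filtered, unfiltered) per-transcript tryptic mc=0 sequence sets."""
    params = DigestParams(enzyme="trypsin", max_missed_cleavages=0)
    _, filt = digest_transcriptome(fx.genes, fx.genome, params)
    _, raw = digest_transcriptome(
        fx.genes, fx.genome, params, apply_length_filter=False
    )
    to_sets = lambda d: {tid: {p.sequence for p in ps} for tid, ps in d.items()}
    return to_sets(filt), to_sets(raw)


def make_mapped(contig: str, start: int, end: int, seq_tag: str = "A") -> MappedPeptide:
    """A single-block mapped peptide covering [start, end); width % 3 == 0."""
    assert (end - start) % 3 == 0
    n = (end - start) // 3
    p = Peptide(
        sequence=seq_tag * n, start=1, end=n, missed_cleavages=0, enzyme="trypsin"
    )
    return MappedPeptide(
        peptide=p, transcript_id="T", blocks=(GenomicBlock(contig, start, end, "+"),)
    )
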