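# Methods

## Coordinate model

All internal coordinates are 0-based half-open on the '+' reference strand.
GTF I/O converts to and from 1-based inclusive at the boundary; BED12 output
is natively 0-based half-open. Transcription order on the '-' strand is
descending genomic order with per-block reverse complementation. The GTF
frame column of the first CDS row in transcription order — not a
recomputation — defines the number of bases trimmed from the 5' end of the
spliced CDS so position 1 starts a codon; a missing frame is assumed 0 with
a warning. Annotated stop codons are kept inside the CDS blocks (rather
than modeled as a separate feature) and a single terminal stop is dropped at
translation; an internal stop truncates the protein and raises a flag
instead of erroring, because annotation-derived CDS can legitimately contain
them (selenoproteins, annotation noise). Codons containing N translate to
'X'; 1–2 trailing leftover nucleotides are ignored with a warning. Deriving
the first-codon offset from the annotation mirrors how translational phase
is carried by GENCODE-style annotations. Transcripts carrying only exon
rows are retained as non-coding: they participate in structure comparison
and event matching but are excluded from digestion.

## Digestion

Cleavage rules are data: a residue set, a cut terminus ('C' = after the
residue, 'N' = before it), and a blocking set. Defaults are the
high-specificity ExPASy-style rules — trypsin K/R‖not-P, LysC K, LysN ‖K,
AspN ‖D, chymotrypsin F/Y/W‖not-P, GluC E — with `chymotrypsin-low` (adds L)
and `gluc-de` (adds D) as named variants, since published usage of these
enzymes varies in exactly these two respects. 'X' and 'U' neither cleave
nor block (conservative behavior on ambiguity). With `max_missed_cleavages
= k`, every concatenation of up to k+1 adjacent zero-missed-cleavage
fragments is emitted, annotated with its missed-cleavage count; the default
length filter keeps 6–60 residues, the usual MS-detectable window. Two
database regimes are built by the batch layer: full digestion (k = 0) and
k ≤ 2. Peptides are position-anchored records (mapping needs residue
coordinates); specificity analysis deduplicates by sequence. Isoleucine
and leucine are distinct by default — sequence letters are taken literally —
with an opt-in I=L collapse for mass-spectrometric indistinguishability.

The digester is validated against an independent brute-force oracle
(enumerate all substrings whose boundaries are cut sites or termini, count
internal sites as missed cleavages) over seeded random proteins for all six
proteases and k ∈ {0, 1, 2}, plus tiling/adjacency/monotonicity property
tests.

## Peptide-to-genome mapping

Residue span [i, j] → CDS nucleotides [3i−2, 3j] → a cumulative-width walk
over CDS blocks in transcription order, offset by the frame trim. A
peptide maps to one genomic block per CDS block touched; ≥ 2 blocks flags a
junction-spanning peptide. Blocks are kept in transcription order
internally; BED12 export re-sorts to ascending genomic order as that format
requires. Two global symmetries are asserted in tests: splicing and
translating the mapped blocks of any peptide recovers its sequence on both
strands, and reverse-complementing the whole genome with flipped
annotations (the "mirror" transform) preserves all proteins and peptide
sets while exactly mirroring every block.

## Specificity, similarity, coverage

Classification is relative to an explicit isoform selection: present in one
selected transcript → *unique*; in all (≥ 2) → *universal*; otherwise
*shared*. A single-transcript selection labels everything *unique* — the
actionable reading for targeted-MS design, where the three-way rule is
otherwise degenerate. Presence is position-agnostic exact sequence
membership in the digest. Jaccard similarity and merged-interval coverage
follow the standard definitions; J is defined 0 when both sets are empty.
Protease comparison digests all coding isoforms of a gene per enzyme and
reports the target transcript's coverage, unique-peptide count and distinct
peptide total.

## AS events

`derive_events` compares exon chains pairwise: SE is one extra internal
exon between shared flanking junctions; RI is one exon spanning two exons
plus the intervening intron with shared outer boundaries (the alternative
region is the intron); A5SS/A3SS is exactly one differing exon boundary,
named by transcription side using strand (5' = donor side); MXE is one
fully disjoint middle exon each at the same slot between shared flanks,
with the convention that the *inclusion* form carries the genomically first
of the two exons. More exotic pairwise differences yield no event rather
than a guess. Duplicate events (type + regions) merge their transcript
sets.

rMATS tables are read in their native 0-based half-open `*_0base`
convention; the A5SS/A3SS alternative region is the set difference of the
long and short exon spans, and the RI region is the intron between the
flanking exon ends. The SplAdder reader accepts a documented simplified
dialect — `contig, strand, event_id, gene_name, alt1_start/alt1_end`
(1-based inclusive; `alt2_*` for MXE) — with the event type encoded in the
`event_id` prefix (`exon_skip`, `intron_retention`, `mutex_exons`,
`alt_3prime`, `alt_5prime`).

Matching an external event to a gene: inclusion isoforms cover every
alternative region completely with exonic bases; exclusion isoforms overlap
the flank-to-flank locus but are exonically disjoint from the regions;
partial coverers are reported as ambiguous and join neither set. MXE is
necessarily special-cased (no single isoform covers both regions):
inclusion covers the first region and avoids the second, exclusion the
reverse. Peptide classification compares the *unions* of the inclusion and
exclusion transcripts' digests — one classification per event. Region
translation locates the region on the cumulative spliced-CDS axis of an
inclusion isoform (falling back to any coding isoform, which the second MXE
region requires), trims to complete codons, and translates; regions outside
every CDS are reported non-coding.

Detectability is a trichotomy: *detectable* if the length-filtered digests
yield differential peptides; otherwise *no_differential_peptide* if even
the unfiltered digests are identical across the event; otherwise
*length_out_of_range*. Relaxing the window to [1, ∞) therefore flips
exactly the third class to detectable, which the tests assert.

## Novel isoforms

External spliced aligners and ORF predictors are deliberately not
reimplemented; the pipeline's substance is ORF → digestion → comparison.
Placement accepts a user exon structure (validated base-by-base against the
cDNA, reporting the first mismatch) or an exact-match search against the
annotated transcripts (equality or substring of a spliced sequence); an
unplaceable cDNA returns a distinguished "unplaced" result directing the
user to an external aligner. The ORF call scans the three forward frames
(cDNA assumed stranded, as for long-read isoforms; a reverse-scan flag
exists): the longest complete ATG..stop ORF encoding ≥ `min_codons`
residues wins, ties broken 5'-most; failing that, the longest ATG-to-end
open span is returned flagged incomplete; failing that, the longest
complete ORF below the threshold. `min_codons` defaults to 30 — small
enough for compact test genes, configurable for real data. Reference
ranking uses Jaccard over merged exonic genomic base coverage (the notion of
"structurally similar" made explicit), ties lexicographic on transcript id.
Novel-specific peptides are those labeled unique to the novel isoform over
the {novel} ∪ references selection.

## Peptide search

The built-in engine is an exact/Hamming window scan — short-peptide lookup
is effectively exact-match, and this keeps the core deterministic and
dependency-free; gapped alignment and E-value statistics are out of scope.
Non-enzymatic matching is the default (immunopeptidome use case); an
enzymatic constraint keeps only windows whose boundaries are cut sites or
protein termini with ≤ 2 internal sites. Identity is
(length − mismatches)/length; ranking is identity-descending, then
transcript id, truncated to `max_targets`. Hit bundles group by gene and
include sibling isoforms lacking the match as context.

## Layout and rendering

Stacking is greedy first-fit over peptides sorted by (outer span start,
span end, sequence) — deterministic and order-independent, with the
invariant that no two row-mates overlap. Greedy stacking does not promise
the chromatic-number optimum; the guaranteed bounds are row count ≤ peptide
count and determinism. Junction peptides occupy one row (overlap on the
outer span), matching track-plot convention. Rendering is static
SVG/PDF via matplotlib; every drawn element, with its hover fields
(sequence, genomic span, enzyme, specificity), is also written to a
companion TSV, which is the machine-testable surface. The palette is a
config value.

## The synthetic fixture

The generator designs proteins first and reverse-translates them with a
fixed codon table, so every planted peptide has known sequence, length and
specificity; introns, UTRs and padding are seeded random DNA scrubbed of
ATG so that ORF prediction on any spliced transcript recovers exactly the
annotated CDS. One gene per contig:

- **GSE** ('+'): cassette exon whose junction-crossing tryptic peptide
  `SQLNDAGVTR` (10 aa) exists only on inclusion; exclusion creates the novel
  junction peptide `SQEILNSGK`. The protein contains no F/Y/W and is 71 aa,
  so chymotrypsin yields a single over-length fragment — the planted
  protease contrast. An unannotated 30-nt exon in intron 2 (tryptic peptide
  `GLNVDDSSTK`) plus the cDNA through it is the novel-isoform substrate,
  and `DSSTNPLEIK` is planted in both isoforms as the search query.
- **GRI** ('−'): retained intron, 9 in-frame stop-free codons; differential
  peptides on both sides of the event.
- **GA5 / GA3** ('+'): 18-nt donor/acceptor extensions giving 12–13 aa vs
  6–7 aa differential tryptic peptides.
- **GMXE** ('+'): two mutually exclusive 24-nt exons, 8-aa differential
  peptides each.
- **GU3** ('+'): a skipped exon entirely within the 3'UTR — identical
  proteins, hence *no_differential_peptide*.
- **GSH** ('+'): a cassette exon `VTAKLDK` flanked by cleavage sites, so
  the only differential tryptic fragments are `VTAK` (4 aa) and `LDK`
  (3 aa) — *length_out_of_range* under the 6–60 window.

The fixture emulates structure, strandedness, frames and event geometry; it
does not emulate chromosome-scale annotation volume, overlapping genes,
annotation noise (e.g. incomplete-CDS tags), or sequence composition bias.
Passing tests therefore certify the coordinate arithmetic, set logic and
rule engines exactly, but say nothing about throughput at genome scale or
robustness to malformed third-party annotation; full-annotation runs use
the same code paths via the batch layer, unexercised by tests beyond the
fixture scale.

## Numerical and degenerate-input choices

Interval logic is uniformly half-open (abutting intervals do not overlap —
asserted at the event-overlap boundary and in the layout). Empty peptide
lists give coverage 0; empty selections and unknown transcripts are errors;
an event with an empty inclusion or exclusion set classifies as
no-differential rather than erroring in batch summaries, but
`classify_event_peptides` itself raises and points to the matching step.
Determinism everywhere: all randomness is seeded (`numpy` Generator in the
fixture, stdlib `random` in tests); sort keys are total (coordinates, then
sequences, then identifiers).

## Problem sizes

Tests and the acceptance script run entirely at fixture scale: 7 genes, 14
coding transcripts, proteins of 20–81 residues, oracle sweeps of 200 random
proteins/cDNAs and 500 random layouts — chosen as the smallest sizes that
exercise every rule branch while keeping the whole suite in seconds.
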