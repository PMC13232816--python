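# splicepep

Splice-aware in-silico proteolysis: from transcript isoform structures and
alternative-splicing (AS) events to the peptides that could actually be seen
by shotgun mass spectrometry.

## The problem

Alternative splicing produces multiple protein isoforms per gene, but
bottom-up MS proteomics only ever observes proteolytic peptides — and many
splice variants leave no peptide-level trace at all, either because the
event falls in a non-coding region or because every differential fragment
falls outside the MS-detectable length window. `splicepep` answers, for any
genome + GTF annotation:

- which peptides a protease digest produces per isoform, and where each
  peptide sits on the genome (including exon–exon junction-spanning
  peptides, which map to ≥ 2 genomic blocks);
- which peptides are **unique** to one isoform, **shared** by a subset, or
  **universal** across a selection — the basis for targeted-MS (SRM/PRM)
  assay design and isoform-specific antibody epitopes;
- whether a given AS event (skipped exon SE, retained intron RI, mutually
  exclusive exons MXE, alternative 5'/3' splice sites A5SS/A3SS) is
  *detectable*, has *no differential peptide*, or is *length-limited*;
- which peptides distinguish a **novel isoform** (e.g. from long-read
  sequencing) from its structurally closest annotated references;
- which isoforms encode an arbitrary **query peptide** (non-enzymatic by
  default, for immunopeptidome use cases).

## Core definitions

Digestion follows residue-specific cleavage rules (`trypsin` C-side of K/R
blocked by P, `lysc`, `lysn`, `aspn`, `chymotrypsin`, `gluc`); with up to
*k* missed cleavages, every concatenation of ≤ *k*+1 adjacent fragments is a
peptide, filtered to the MS-detectable 6–60 residue window by default.
Residue span [i, j] maps to CDS nucleotides [3i−2, 3j], which walk through
the CDS blocks in transcription order to genomic blocks. For two isoform
peptide sets A, B the similarity is the Jaccard coefficient
J(A,B) = |A∩B| / |A∪B|; per-protein coverage is the merged-span residue
fraction. For an event with inclusion-digest union I and exclusion-digest
union X, the differential peptides are I∖X and X∖I; the event is
*detectable* iff one of them is non-empty after length filtering.

## Worked example

```python
import splicepep as sp

fx = sp.generate_fixture(seed=1)
gene = fx.gene("GSE")                       # skipped-exon gene, 2 isoforms

params = sp.DigestParams(enzyme="trypsin")  # full digestion, 6-60 aa window
index, per_t = sp.digest_transcriptome([gene], fx.genome, params)
labels = sp.classify_specificity(index, {"T_SE_INC", "T_SE_EXC"})
print(sorted(s for s, l in labels.items() if l == "unique"))
# ['EILNSGK', 'SQEILNSGK', 'SQLNDAGVTR']

(event,) = sp.derive_events(gene)
print(event.event_type, event.alt_regions[0])
# SE chrSE:245-269(+)

sets = {tid: {p.sequence for p in ps} for tid, ps in per_t.items()}
cls = sp.classify_event_peptides(event, sets)
print(sorted(cls.inclusion_specific), sorted(cls.exclusion_specific))
# ['EILNSGK', 'SQLNDAGVTR'] ['SQEILNSGK']
```

`SQLNDAGVTR` is the 10-residue tryptic peptide straddling the cassette exon:
present only when the exon is included, within the MS length window, so the
event is classified `detectable`. The exclusion isoform instead produces the
novel junction peptide `SQEILNSGK`.

The same analyses are exposed as a CLI:

```sh
splicepep fixtures --seed 1 --out fx/
splicepep digest   --genome fx/fixture_genome.fa --gtf fx/fixture_annotation.gtf \
                   --enzyme trypsin --out peptides.tsv
splicepep events   --genome fx/fixture_genome.fa --gtf fx/fixture_annotation.gtf \
                   --out events.tsv
splicepep search   --genome fx/fixture_genome.fa --gtf fx/fixture_annotation.gtf \
                   --query DSSTNPLEIK --out hits.tsv
```

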