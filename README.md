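# gfml — an interchange toolkit for gene-fusion discovery data

Transcriptome sequencing routinely yields long lists of chimeric-transcript
candidates, but the features that determine whether a candidate matters —
the exon-level breakpoints, the reading frame of the product, the supporting
reads, how (and whether) it was validated — are usually scattered across
paper figures, supplementary tables and ad-hoc caller output. `gfml`
implements a machine-readable interchange format for such data, for
bioinformaticians who need to exchange, validate and query fusion call sets
across studies and tools.

## The data model

A document is a `Record_Set` of one or more self-contained `Record`s. Each
record carries up to **nine element categories**:

| category | role |
|---|---|
| source | publication / data-provider provenance |
| sample | specimen: organism, tissue, disease |
| experiment | design and parameters |
| sequence_platform | sequencing instrument and application |
| validation_platform | orthogonal validation method (FISH, qRT-PCR, …) |
| mapping_algorithm | read mapper and parameters |
| fusion_detection_algorithm | fusion caller and parameters |
| sequence_repository | where the raw reads live |
| gene_fusion | the fusion entries themselves |

**Source, sample and gene fusion are mandatory; the other six are
optional** — but a category that is present must be nonempty ("one to
infinite" cardinality). Every fusion links, by record-scoped identifiers, to
its sample and optionally to the experiment, platform and algorithms that
produced it. A fusion entry holds both partners (chromosome, strand, 1-based
breakpoint, exon context, domain annotations), the splice junction, read
evidence (counts, RPKM and the read sequences themselves, retained so
observations can be independently re-verified), reading-frame status,
inferred mechanism, product class and validation outcomes.

On top of the model the package provides:

* a validator producing machine-readable findings (structural, referential,
  coordinate and controlled-vocabulary checks), plus an exportable **XSD**
  that enforces the structural subset of those rules;
* derived-attribute calculators: GT–AG splice-pattern classification, the
  reading-frame rule (in frame iff the retained 5' coding length mod 3
  equals the native codon phase of the first retained 3' base), breakpoint
  boundary classes against an exon model, and mechanism inference from
  partner geometry (translocation / inversion / deletion / read-through /
  tandem duplication);
* a query engine with a small predicate language covering a catalogue of
  seventeen biologically motivated queries (fusions involving a gene,
  by tissue or disease, broken domains, validation by FISH, non-canonical
  splice patterns, candidates above an RPKM threshold, …);
* converters: generic fusion-caller tables → GFML (via a column map), and
  GFML → BEDPE for interval tooling;
* a seeded synthetic-record generator and defect injector so everything is
  testable offline, including a TMPRSS2–ERG exemplar record.

## Worked example

Generate a small document, summarise and query it:

```sh
$ gfml synth --seed 11 --records 1 --fusions 3 --out demo.xml
$ gfml stats demo.xml
records                      1
source                       1
sample                       1
experiment                   1
sequence_platform            2
validation_platform          2
mapping_algorithm            1
fusion_detection_algorithm   1
sequence_repository          1
gene_fusion                  3
$ gfml validate demo.xml
OK: no findings
$ gfml query demo.xml "evidence.rpkm ge 20"
record_id	fusion_id	gene_5p	gene_3p	query
R1	F1	PRCC	AKT3	evidence.rpkm ge 20
R1	F3	PRCC	BRAF	evidence.rpkm ge 20
```

The stats table shows all nine element categories populated (plus the
record count); the query lists the two of three synthetic fusions whose
expression exceeds 20 RPKM. The same operations are available as library
calls (`generate_record_set`, `record_stats`, `validate`, `run_query`).

The bundled TMPRSS2–ERG exemplar (prostate-cancer fusion, placeholder
coordinates) behaves like a one-fusion study:

```sh
$ gfml query exemplar.xml "gene_symbol equals ERG"
record_id	fusion_id	gene_5p	gene_3p	query
R_TMPRSS2_ERG	F1	TMPRSS2	ERG	gene_symbol equals ERG
$ gfml convert gfml2bedpe exemplar.xml
chr21	42880007	42880008	chr21	39817543	39817544	TMPRSS2--ERG	42	-	-
```

The BEDPE line converts the 1-based closed breakpoints to 0-based
half-open single-base intervals; the score column is the junction read
count.

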