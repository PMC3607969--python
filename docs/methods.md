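# Methods

## The record model

A document is a `Record_Set` holding one or more `Record`s; a record is the
unit of self-containment. It carries nine element categories (source,
sample, experiment, sequencing platform, validation platform, mapping
algorithm, fusion-detection algorithm, sequence repository, gene fusion),
of which source, sample and gene fusion are mandatory. Cardinality is
"one to infinite": an optional category is either absent or nonempty, and
the writer never emits an empty category element — the lenient reader flags
one as `EMPTY_LIST`.

Identifiers are scoped to the record, not the document: element ids must be
unique within a record, fusions reference other elements (`sample_ref`,
`experiment_ref`, …) only within their own record, and only record ids must
be unique set-wide. This keeps records independently exchangeable.

Enumerated fields (mechanism, ORF status, product class, boundary class,
splice pattern, validation method, …) are stored as plain strings and
checked against a controlled-vocabulary registry rather than encoded as
closed Python enums. Two reasons: a lenient reader must be able to
materialise a foreign document containing an out-of-vocabulary term in
order to report it, and the registry is meant to be extended from a
YAML/JSON file as community usage grows. Matching is case-insensitive with
canonical casing on output; a miss is reported with the nearest registry
term by Levenshtein distance (ties broken alphabetically).

### Coordinate conventions

Genomic coordinates are 1-based, fully closed, on the forward strand, with
strand stored separately. The breakpoint of the 5' partner is the last
transcribed base retained in the chimeric transcript; that of the 3'
partner is the first base retained. BEDPE export is the single place where
conversion to 0-based half-open happens (`start = breakpoint − 1`,
`end = breakpoint`).

## Validation and the exported schema

`validate()` turns every problem into a finding `(code, severity, path,
message)` and never raises; findings are sorted by path, code and message
so reports are stable under record/list permutation. `is_valid` means "no
error-severity finding". Vocabulary violations are warnings by default and
become errors under `strict` — the format is deliberately permissive toward
legacy data, and term sets are expected to evolve. Error severity is
reserved for structural damage: missing mandatory categories, empty
category elements, duplicate ids, unresolvable references, non-positive
breakpoints, invalid strands, and a stored splice pattern contradicting its
own dinucleotides.

The exported XSD encodes exactly the structural subset of these rules:
category `minOccurs`, one-to-unbounded children, per-record id uniqueness
(`xs:key`), reference resolution (`xs:keyref`), positive-integer
breakpoints, the `+`/`-` strand enumeration, dinucleotide and read-sequence
patterns, and non-empty required scalars. Vocabulary terms and cross-field
consistency are intentionally left to the programmatic validator, since
XSD 1.0 cannot express them and freezing terms in the schema would defeat
registry extensibility. `STRUCTURAL_CODES` names the finding codes on which
schema and validator are guaranteed to agree; the test suite cross-checks
that guarantee over corpora of valid and deliberately corrupted documents.

A foreign element in an otherwise valid document is preserved verbatim and
reported as an `UNKNOWN_ELEMENT` warning (a reader-level code added beside
the eight validator codes) rather than dropped, so round-tripping a
document from a newer dialect loses nothing.

Deleting a category from a record — the operation behind the
mandatory-category count — is implemented semantically by `drop_category`:
removing the elements also clears the optional references that pointed at
them (a record without validation platforms has no validation links
either). The mandatory `sample_ref` is never cleared, so dropping samples
leaves the record genuinely broken. This isolates what the count measures —
mandatoriness — from referential side effects of the deletion itself.

## Derived attributes

**Splice pattern.** Canonical ⇔ donor `GT` and acceptor `AG`. The
minor-spliceosome pairs `GC–AG` and `AT–AC` are classified non-canonical
(they are rare enough that flagging them for review is the useful
behaviour) and recognised in an informational note.

**Reading frame.** The rule operates on two quantities fixed by exon-level
junction coordinates: `L`, the coding bases retained by the 5' partner
(start codon to breakpoint inclusive), and `p ∈ {0,1,2}`, the native codon
phase of the first retained coding base of the 3' partner. The fusion is in
frame iff `L mod 3 = p` — the ribosome reaches the junction in the
sub-codon position the 3' exon expects. `L = 0` with a coding 3' segment is
a promoter swap; a non-coding 3' segment is non-coding; missing annotation
falls through to unknown. The suite verifies the rule against an
independent oracle that concatenates toy CDS fragments at randomized
junctions, translates them, and asks whether the distal 3' peptide
survives.

**Product class.** In frame → fusion protein; out of frame → truncated
protein (the 5' moiety terminates shortly after the junction); promoter
swap and non-coding map to themselves.

**Boundary class.** Against a sorted exon model (1-based closed, loadable
from BED with the usual 0-based half-open conversion): exact exon
start/end → `exon_boundary`; strictly inside an exon → `within_exon`;
inside the gene span otherwise → `intronic`; outside → `intergenic`; empty
model → `unknown`.

**Mechanism.** From partner geometry alone: different chromosomes →
translocation; same chromosome, opposite strands → inversion; same
chromosome and strand with the 5' breakpoint upstream (in transcription
direction) → deletion-like, reported as `read_through` when the gap is
below the adjacency threshold and `deletion` otherwise; 5' downstream →
tandem duplication. The threshold defaults to 1 Mb — generous for
adjacent-gene read-through — and is a parameter. Trans-splicing cannot be
inferred from geometry; it exists only as an annotated value.

## Queries

Atoms pair a registered selector with an operator; `equals` is
case-insensitive exact (numeric when both sides parse), `contains` is
case-insensitive substring (used for free-text fields such as disease and
author), `ge`/`le` are numeric, `exists` tests presence, `in_set` is
membership. Absent optional fields match nothing except `exists false`.
Reference-backed selectors resolve through the record; a fusion whose
evaluation hits a dangling reference is excluded with a warning rather than
failing the query. "Sequence evidence" in the prebuilt catalogue means at
least one stored read sequence (`evidence.reads ge 1`), not merely a
populated evidence block; the expression-threshold entry applies to RPKM,
with the unique-read-count selector exposed separately since either reading
of that row is defensible. The engine is an unoptimized per-fusion scan by
design; correctness is checked against an independent flattened-dictionary
evaluator.

## The synthetic generator

The generator emulates the *structure* of NGS fusion-discovery studies so
that validation, round-tripping, schema agreement and queries can be tested
offline. Defaults: 3 records × 5 fusions; 30 % of candidates in frame
(candidate lists are mostly frame-disrupting); 80 % carrying read evidence
(retaining reads is the format's point, but not universal); 25 %
orthogonally validated; 80 % canonical junctions; mechanisms weighted
translocation 0.35, deletion 0.2, inversion 0.15, read-through 0.1, tandem
duplication 0.1, trans-splicing 0.05 — a plausible mix for transcriptome
call sets. Reads are uniform-random 50-mers.

Internal consistency is maintained where it affects downstream semantics:
partner geometry is sampled to reproduce the drawn mechanism, junction
dinucleotides agree with the stored pattern, and product class follows
frame status. What the generator does **not** emulate: gene symbols are
drawn from a bundled list of ~50 recurrent fusion partners with no link to
their true loci; coordinates are uniform over a toy chromosome-length
table; read sequences have no relation to any genome. Passing tests
therefore demonstrate the correctness of the format machinery — parsing,
validation, reference resolution, query semantics, schema agreement — not
biological plausibility of any particular record.

`corrupt()` serialises a set and injects exactly one defect kind
(deterministic per seed) at the document level, one injector per finding
code, so the defect↔code correspondence and the schema/validator agreement
can be exercised mechanically.

## Numerical and scale choices

Serialisation is deterministic (fixed element/attribute order, UTF-8,
pretty-printed, `repr`-formatted floats) so writing is a byte-level
fixpoint after one round-trip. The suite exercises round-tripping over 100
seeds at 2 records × 3 fusions, schema agreement over 400 documents, query
equivalence on a 1 000-fusion set, and the frame rule on 500 random
junctions — sizes chosen so the whole suite runs in seconds while every
code path and defect kind is covered many times over.

## Limitations

No semantic validation against external annotation (gene symbols, exon
coordinates vs a GTF) and no identifier mapping across annotation
namespaces. Domain retained/broken/lost status is input data, not computed.
The XSD reconstructs attribute-level detail from the element model and may
differ from other dialects in which scalars are required. No VCF BND
export, no compression handling, and the reader is DOM-based — documents
are assumed to fit comfortably in memory.
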