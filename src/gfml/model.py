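"""Domain model for gene-fusion interchange records.

A :class:`RecordSet` is the document root; each :class:`Record` is a
self-contained study unit carrying up to nine element categories (source,
sample, experiment, sequencing platform, validation platform, mapping
algorithm, fusion-detection algorithm, sequence repository, gene fusion).
Three categories — source, sample and gene fusion — are mandatory; the
rest are optional, but a category that is present must be nonempty.

The dataclasses here are deliberately permissive containers: range and
vocabulary rules are enforced by :func:`gfml.validation.validate`, so a
lenient reader can materialise structurally deficient documents and report
on them instead of refusing to load.  The checked entry point for building
records programmatically is :func:`new_record`, which rejects empty
mandatory categories and duplicate identifiers up front.

Coordinates are 1-based, fully closed, on the forward genomic strand; the
strand is recorded separately.  On the 5' partner the breakpoint is the
last transcribed base retained; on the 3' partner it is the first base
retained.  Conversion to 0-based half-open happens only in BEDPE export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

__all__ = [
    "GfmlError",
    "ConstructionError",
    "CATEGORIES",
    "MANDATORY_CATEGORIES",
    "RecordSet",
    "Record",
    "SourceInfo",
    "SampleInfo",
    "ExperimentInfo",
    "SequencePlatform",
    "ValidationPlatform",
    "MappingAlgorithm",
    "FusionDetectionAlgorithm",
    "SequenceRepository",
    "FusionPartner",
    "DomainAnnotation",
    "SpliceJunction",
    "ReadEvidence",
    "ValidationResult",
    "GeneFusion",
    "new_record",
    "resolve_reference",
    "record_stats",
    "drop_category",
]


class GfmlError(Exception):
    """Base class for errors raised by this package."""


class ConstructionError(GfmlError):
    """A record or record set violates a structural construction rule."""

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"{code}: {message}")


# The nine element categories a Record can carry, in canonical document
# order.  Keys are Record attribute names; values are element-style labels.
CATEGORIES: tuple[tuple[str, str], ...] = (
    ("sources", "source"),
    ("samples", "sample"),
    ("experiments", "experiment"),
    ("sequence_platforms", "sequence_platform"),
    ("validation_platforms", "validation_platform"),
    ("mapping_algorithms", "mapping_algorithm"),
    ("fusion_detection_algorithms", "fusion_detection_algorithm"),
    ("sequence_repositories", "sequence_repository"),
    ("gene_fusions", "gene_fusion"),
)

CATEGORY_LABELS: tuple[str, ...] = tuple(label for _, label in CATEGORIES)

MANDATORY_CATEGORIES: frozenset[str] = frozenset(
    {"source", "sample", "gene_fusion"}
)

# Closed term sets for the enumerated fields.  Values are stored as plain
# strings so that out-of-vocabulary terms read from a foreign document can
# be represented and reported rather than rejected at parse time.
SOURCE_TYPES = ("publication", "data_provider")
SAMPLE_CLASSES = ("tissue", "cell_line", "xenograft", "other")
PARTNER_ROLES = ("five_prime", "three_prime")
STRANDS = ("+", "-")
BOUNDARY_CLASSES = ("exon_boundary", "within_exon", "intronic", "intergenic", "unknown")
DOMAIN_STATUSES = ("retained", "broken", "lost")
SPLICE_PATTERNS = ("canonical", "non_canonical", "unknown")
ORF_STATUSES = ("in_frame", "out_of_frame", "promoter_swap", "non_coding", "unknown")
MECHANISMS = (
    "translocation",
    "inversion",
    "deletion",
    "tandem_duplication",
    "read_through",
    "trans_splicing",
    "unknown",
)
PRODUCT_CLASSES = (
    "fusion_protein",
    "truncated_protein",
    "promoter_swap",
    "non_coding",
    "unknown",
)
VALIDATION_OUTCOMES = ("validated", "not_validated", "untested")


@dataclass
class SourceInfo:
    """Publication or data-provider provenance for a record."""

    id: str
    source_type: str = "publication"
    pubmed_id: Optional[str] = None
    title: Optional[str] = None
    authors: list[str] = field(default_factory=list)
    year: Optional[int] = None
    contact: Optional[str] = None


@dataclass
class SampleInfo:
    """Biological specimen the fusions were observed in."""

    id: str
    organism: str = "Homo sapiens"
    tissue_type: str = ""
    disease: Optional[str] = None
    sample_class: str = "tissue"
    description: Optional[str] = None


@dataclass
class ExperimentInfo:
    id: str
    title: Optional[str] = None
    design_description: Optional[str] = None
    parameters: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class SequencePlatform:
    id: str
    name: str = ""
    description: Optional[str] = None
    application_type: str = "transcriptome"


@dataclass
class ValidationPlatform:
    id: str
    method: str = ""
    description: Optional[str] = None


@dataclass
class MappingAlgorithm:
    id: str
    name: str = ""
    version: Optional[str] = None
    parameters: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class FusionDetectionAlgorithm:
    id: str
    name: str = ""
    version: Optional[str] = None
    parameters: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class SequenceRepository:
    id: str
    name: str = ""
    accession: Optional[str] = None
    uri: Optional[str] = None


@dataclass
class DomainAnnotation:
    """A protein functional domain and its fate in the fusion product."""

    name: str
    accession: Optional[str] = None
    status: str = "retained"


@dataclass
class FusionPartner:
    """One side of a fusion: gene, genomic breakpoint and local context.

    ``breakpoint`` is 1-based on the forward strand.  For the 5' partner it
    is the last transcribed base retained in the chimeric transcript; for
    the 3' partner it is the first base retained.
    """

    role: str
    gene_symbol: str
    chromosome: str
    strand: str
    breakpoint: int
    gene_accession: Optional[tuple[str, str]] = None
    transcript_accession: Optional[str] = None
    exon_number: Optional[int] = None
    boundary_class: str = "unknown"
    domains: list[DomainAnnotation] = field(default_factory=list)


@dataclass
class SpliceJunction:
    """Splice-level description of the fusion junction.

    ``pattern`` should agree with the GT–AG rule when both dinucleotides
    are present; the validator flags disagreements.
    """

    donor_dinucleotide: Optional[str] = None
    acceptor_dinucleotide: Optional[str] = None
    pattern: str = "unknown"
    junction_sequence: Optional[str] = None


@dataclass
class ReadEvidence:
    """Sequencing support for a fusion, retained for reanalysis."""

    junction_read_count: int = 0
    spanning_pair_count: int = 0
    rpkm: Optional[float] = None
    unique_read_count: Optional[int] = None
    reads: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class ValidationResult:
    platform_ref: Optional[str] = None
    outcome: str = "untested"
    note: Optional[str] = None


@dataclass
class GeneFusion:
    """A single fusion entry linking two partners with study context.

    The ``*_ref`` fields point, by identifier, at elements of the other
    categories within the enclosing record; ``sample_ref`` is mandatory.
    """

    id: str
    five_prime: FusionPartner
    three_prime: FusionPartner
    sample_ref: str = ""
    junction: Optional[SpliceJunction] = None
    evidence: Optional[ReadEvidence] = None
    orf_status: str = "unknown"
    mechanism: str = "unknown"
    product_class: str = "unknown"
    validations: list[ValidationResult] = field(default_factory=list)
    experiment_ref: Optional[str] = None
    mapping_algorithm_ref: Optional[str] = None
    fusion_detection_algorithm_ref: Optional[str] = None
    sequence_platform_ref: Optional[str] = None

    def refs(self) -> Iterator[tuple[str, str]]:
        """Yield (field name, target id) for every populated reference."""
        for name in (
            "sample_ref",
            "experiment_ref",
            "mapping_algorithm_ref",
            "fusion_detection_algorithm_ref",
            "sequence_platform_ref",
        ):
            value = getattr(self, name)
            if value:
                yield name, value
        for i, v in enumerate(self.validations):
            if v.platform_ref:
                yield f"validations[{i}].platform_ref", v.platform_ref


Element = Union[
    SourceInfo,
    SampleInfo,
    ExperimentInfo,
    SequencePlatform,
    ValidationPlatform,
    MappingAlgorithm,
    FusionDetectionAlgorithm,
    SequenceRepository,
    GeneFusion,
]


@dataclass
class Record:
    """A self-contained unit of fusion entries from one or more sources.

    Identifiers are scoped to the record: element ids must be unique within
    it, and references never cross record boundaries.  An optional category
    is either absent (empty list here) or nonempty — writers never emit an
    empty category element.
    """

    id: str
    sources: list[SourceInfo] = field(default_factory=list)
    samples: list[SampleInfo] = field(default_factory=list)
    experiments: list[ExperimentInfo] = field(default_factory=list)
    sequence_platforms: list[SequencePlatform] = field(default_factory=list)
    validation_platforms: list[ValidationPlatform] = field(default_factory=list)
    mapping_algorithms: list[MappingAlgorithm] = field(default_factory=list)
    fusion_detection_algorithms: list[FusionDetectionAlgorithm] = field(
        default_factory=list
    )
    sequence_repositories: list[SequenceRepository] = field(default_factory=list)
    gene_fusions: list[GeneFusion] = field(default_factory=list)
    # serialized foreign elements preserved by the lenient reader
    extra_xml: list[str] = field(default_factory=list)

    def category(self, label: str) -> list:
        """Return the element list for a category label (e.g. ``sample``)."""
        for attr, lab in CATEGORIES:
            if lab == label:
                return getattr(self, attr)
        raise KeyError(label)

    def elements(self) -> Iterator[tuple[str, Element]]:
        """Yield (category label, element) over all nine categories."""
        for attr, label in CATEGORIES:
            for el in getattr(self, attr):
                yield label, el

    def populated_categories(self) -> list[str]:
        """Labels of the categories carrying at least one element."""
        return [label for attr, label in CATEGORIES if getattr(self, attr)]


@dataclass
class RecordSet:
    """Document root: one or more records plus a format version label."""

    records: list[Record]
    format_version: str = "prototype-1"


def new_record(
    id: str,
    sources: list[SourceInfo],
    samples: list[SampleInfo],
    gene_fusions: list[GeneFusion],
    *,
    experiments: Optional[list[ExperimentInfo]] = None,
    sequence_platforms: Optional[list[SequencePlatform]] = None,
    validation_platforms: Optional[list[ValidationPlatform]] = None,
    mapping_algorithms: Optional[list[MappingAlgorithm]] = None,
    fusion_detection_algorithms: Optional[list[FusionDetectionAlgorithm]] = None,
    sequence_repositories: Optional[list[SequenceRepository]] = None,
) -> Record:
    """Build a record, enforcing the mandatory-category and unique-id rules.

    Raises
    ------
    ConstructionError
        With code ``MISSING_MANDATORY`` if any of the source, sample or
        gene-fusion lists is empty, or ``DUPLICATE_ID`` if two elements in
        the record share an identifier.
    """
    record = Record(
        id=id,
        sources=list(sources),
        samples=list(samples),
        experiments=list(experiments or []),
        sequence_platforms=list(sequence_platforms or []),
        validation_platforms=list(validation_platforms or []),
        mapping_algorithms=list(mapping_algorithms or []),
        fusion_detection_algorithms=list(fusion_detection_algorithms or []),
        sequence_repositories=list(sequence_repositories or []),
        gene_fusions=list(gene_fusions),
    )
    for attr, label in CATEGORIES:
        if label in MANDATORY_CATEGORIES and not getattr(record, attr):
            raise ConstructionError(
                "MISSING_MANDATORY",
                f"record {id!r} has no {label} element; "
                f"source, sample and gene_fusion are mandatory",
            )
    seen: set[str] = set()
    for label, el in record.elements():
        if el.id in seen:
            raise ConstructionError(
                "DUPLICATE_ID",
                f"identifier {el.id!r} occurs more than once in record {id!r}",
            )
        seen.add(el.id)
    return record


def resolve_reference(record: Record, ref: str) -> Optional[Element]:
    """Return the element of ``record`` with identifier ``ref``, or None.

    All nine categories are searched; construction guarantees at most one
    match.
    """
    for _, el in record.elements():
        if el.id == ref:
            return el
    return None


def record_stats(record_set: RecordSet) -> dict[str, int]:
    """Per-category element counts across the whole set.

    Returns a mapping with a ``records`` entry followed by the nine
    category labels in canonical order, each giving the total element count
    summed over records.
    """
    stats: dict[str, int] = {"records": len(record_set.records)}
    for attr, label in CATEGORIES:
        stats[label] = sum(len(getattr(r, attr)) for r in record_set.records)
    return stats


def drop_category(record: Record, label: str) -> Record:
    """Return a copy of ``record`` with one element category removed.

    Removing a category also removes anything that referenced it: optional
    ``*_ref`` fields pointing into the dropped category are cleared, and
    validation results lose their platform link when validation platforms
    are dropped.  The mandatory ``sample_ref`` is never cleared, so
    dropping the sample category leaves the record genuinely broken.
    """
    import copy

    rec = copy.deepcopy(record)
    dropped_ids = {el.id for el in rec.category(label)}
    rec.category(label).clear()
    ref_field_by_label = {
        "experiment": "experiment_ref",
        "mapping_algorithm": "mapping_algorithm_ref",
        "fusion_detection_algorithm": "fusion_detection_algorithm_ref",
        "sequence_platform": "sequence_platform_ref",
    }
    optional_ref = ref_field_by_label.get(label)
    for fusion in rec.gene_fusions:
        if optional_ref and getattr(fusion, optional_ref) in dropped_ids:
            setattr(fusion, optional_ref, None)
        if label == "validation_platform":
            fusion.validations = [
                v for v in fusion.validations if v.platform_ref not in dropped_ids
            ]
    return rec
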