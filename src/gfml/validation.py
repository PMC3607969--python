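"""Structural, referential and vocabulary validation.

All problems are reported as findings, never raised: :func:`validate`
walks a :class:`~gfml.model.RecordSet` and returns a
:class:`ValidationReport` whose findings are stably sorted by record,
path and code.  Vocabulary violations are warnings by default — the
format is deliberately flexible toward legacy data — and become errors
under ``strict=True``.

The controlled vocabularies live in a :class:`VocabularyRegistry` that
matches case-insensitively, returns canonical casing, and can be
extended or replaced from a YAML/JSON file so communities can grow the
term sets.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import model
from .model import CATEGORIES, MANDATORY_CATEGORIES, GfmlError, Record, RecordSet

__all__ = [
    "FINDING_CODES",
    "ValidationFinding",
    "ValidationReport",
    "VocabularyRegistry",
    "VocabularyError",
    "DEFAULT_REGISTRY",
    "check_vocabulary",
    "validate",
]

FINDING_CODES = (
    "MISSING_MANDATORY",
    "EMPTY_LIST",
    "DUPLICATE_ID",
    "DANGLING_REF",
    "VOCAB_VIOLATION",
    "COORD_INVALID",
    "STRAND_INVALID",
    "PATTERN_MISMATCH",
    # emitted by the lenient reader for preserved foreign elements
    "UNKNOWN_ELEMENT",
)

_DINUCLEOTIDE = re.compile(r"^[ACGT]{2}$", re.IGNORECASE)
_READ_SEQ = re.compile(r"^[ACGTN]+$", re.IGNORECASE)
# conventional chromosome labels: optional chr prefix, 1-22/X/Y/M/MT
_CHROM = re.compile(r"^(chr)?([1-9]|1[0-9]|2[0-2]|X|Y|MT?)$", re.IGNORECASE)


@dataclass(frozen=True)
class ValidationFinding:
    code: str
    severity: str  # "error" | "warning"
    path: str  # record id + element path, e.g. "R1/gene_fusion[F2]/five_prime"
    message: str

    def as_dict(self) -> dict[str, str]:
        return {
            "code": self.code,
            "severity": self.severity,
            "path": self.path,
            "message": self.message,
        }


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    def codes(self) -> set[str]:
        return {f.code for f in self.findings}

    def error_codes(self) -> set[str]:
        return {f.code for f in self.findings if f.severity == "error"}

    def sorted(self) -> "ValidationReport":
        key = lambda f: (f.path, f.code, f.message)
        return ValidationReport(findings=sorted(self.findings, key=key))

    def merged(self, other: "ValidationReport") -> "ValidationReport":
        return ValidationReport(self.findings + other.findings).sorted()

    def to_json(self) -> str:
        return json.dumps(
            {
                "is_valid": self.is_valid,
                "findings": [f.as_dict() for f in self.findings],
            },
            indent=2,
        )

    def to_text(self) -> str:
        if not self.findings:
            return "OK: no findings\n"
        lines = [
            f"{f.severity.upper():7s} {f.code:17s} {f.path}: {f.message}"
            for f in self.findings
        ]
        verdict = "valid" if self.is_valid else "INVALID"
        lines.append(f"-- {len(self.findings)} finding(s); document is {verdict}")
        return "\n".join(lines) + "\n"


class VocabularyError(GfmlError):
    """An unknown vocabulary name was requested."""


#: Seed vocabularies.  The term content is an initial standardisation —
#: validation methods and platform applications reflect the techniques in
#: common use for fusion discovery and confirmation — and is expected to be
#: extended from a registry file as the format is adopted.
_DEFAULT_VOCABULARIES: dict[str, tuple[str, ...]] = {
    "validation_methods": (
        "FISH",
        "qRT-PCR",
        "RT-PCR",
        "qPCR",
        "Sanger",
        "aCGH",
        "immunoblot",
    ),
    "platform_applications": ("transcriptome", "genome", "exome", "targeted"),
    "mechanisms": model.MECHANISMS,
    "orf_statuses": model.ORF_STATUSES,
    "splice_patterns": model.SPLICE_PATTERNS,
    "boundary_classes": model.BOUNDARY_CLASSES,
    "product_classes": model.PRODUCT_CLASSES,
    "sample_classes": model.SAMPLE_CLASSES,
    "source_types": model.SOURCE_TYPES,
    "domain_statuses": model.DOMAIN_STATUSES,
    "validation_outcomes": model.VALIDATION_OUTCOMES,
    "partner_roles": model.PARTNER_ROLES,
}


def _edit_distance(a: str, b: str) -> int:
    # Levenshtein distance, small inputs only (registry terms are short).
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@dataclass
class VocabularyCheck:
    ok: bool
    canonical: Optional[str] = None
    suggestion: Optional[str] = None


class VocabularyRegistry:
    """Named controlled-vocabulary term sets with case-insensitive lookup."""

    def __init__(self, vocabularies: Optional[dict[str, Iterable[str]]] = None):
        source = vocabularies if vocabularies is not None else _DEFAULT_VOCABULARIES
        self._vocabularies: dict[str, list[str]] = {}
        for name, terms in source.items():
            terms = list(terms)
            if not terms:
                raise ValueError(f"vocabulary {name!r} must be nonempty")
            self._vocabularies[name] = terms

    def names(self) -> list[str]:
        return sorted(self._vocabularies)

    def terms(self, vocabulary_name: str) -> list[str]:
        try:
            return list(self._vocabularies[vocabulary_name])
        except KeyError:
            raise VocabularyError(
                f"unknown vocabulary {vocabulary_name!r}; "
                f"known vocabularies: {', '.join(self.names())}"
            ) from None

    def check(self, term: str, vocabulary_name: str) -> VocabularyCheck:
        """Case-insensitive membership; on a miss, suggest the nearest term.

        Ties on edit distance break alphabetically.
        """
        terms = self.terms(vocabulary_name)
        for t in terms:
            if t.lower() == (term or "").lower():
                return VocabularyCheck(ok=True, canonical=t)
        if not term:
            return VocabularyCheck(ok=False)
        best = min(sorted(terms), key=lambda t: _edit_distance(term.lower(), t.lower()))
        return VocabularyCheck(ok=False, suggestion=best)

    def extend(self, vocabulary_name: str, terms: Iterable[str]) -> None:
        existing = self._vocabularies.setdefault(vocabulary_name, [])
        lowered = {t.lower() for t in existing}
        for t in terms:
            if t.lower() not in lowered:
                existing.append(t)
                lowered.add(t.lower())

    @classmethod
    def from_file(cls, path: str, base: Optional["VocabularyRegistry"] = None):
        """Load name→terms from YAML or JSON, layered over ``base``.

        Terms in the file extend (not replace) any vocabulary of the same
        name in ``base``; new names are added as-is.
        """
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise GfmlError(f"vocabulary file {path!r} must map names to term lists")
        registry = cls(dict(_DEFAULT_VOCABULARIES)) if base is None else base
        for name, terms in data.items():
            if not isinstance(terms, list):
                raise GfmlError(f"vocabulary {name!r} in {path!r} is not a list")
            registry.extend(name, [str(t) for t in terms])
        return registry


DEFAULT_REGISTRY = VocabularyRegistry()


def check_vocabulary(
    term: str,
    vocabulary_name: str,
    registry: Optional[VocabularyRegistry] = None,
) -> VocabularyCheck:
    """Check ``term`` against a named vocabulary of the (default) registry."""
    return (registry or DEFAULT_REGISTRY).check(term, vocabulary_name)


class _Collector:
    def __init__(self, strict: bool, registry: VocabularyRegistry):
        self.strict = strict
        self.registry = registry
        self.findings: list[ValidationFinding] = []

    def add(self, code: str, severity: str, path: str, message: str) -> None:
        self.findings.append(ValidationFinding(code, severity, path, message))

    def vocab(self, term: Optional[str], vocabulary_name: str, path: str) -> None:
        if term is None:
            return
        result = self.registry.check(term, vocabulary_name)
        if not result.ok:
            hint = f" (did you mean {result.suggestion!r}?)" if result.suggestion else ""
            self.add(
                "VOCAB_VIOLATION",
                "error" if self.strict else "warning",
                path,
                f"{term!r} is not a {vocabulary_name} term{hint}",
            )


def _check_partner(c: _Collector, partner: model.FusionPartner, path: str) -> None:
    if not partner.gene_symbol:
        c.add("MISSING_MANDATORY", "error", path, "gene symbol is empty")
    if partner.breakpoint is None or partner.breakpoint < 1:
        c.add(
            "COORD_INVALID",
            "error",
            path,
            f"breakpoint {partner.breakpoint!r} must be a 1-based coordinate",
        )
    if not partner.chromosome:
        c.add("COORD_INVALID", "error", path, "chromosome label is empty")
    elif not _CHROM.match(partner.chromosome):
        c.add(
            "COORD_INVALID",
            "warning",
            path,
            f"chromosome label {partner.chromosome!r} is unconventional",
        )
    if partner.strand not in model.STRANDS:
        c.add(
            "STRAND_INVALID",
            "error",
            path,
            f"strand {partner.strand!r} is not '+' or '-'",
        )
    if partner.exon_number is not None and partner.exon_number < 1:
        c.add("COORD_INVALID", "error", path, f"exon number {partner.exon_number} < 1")
    c.vocab(partner.role, "partner_roles", path)
    c.vocab(partner.boundary_class, "boundary_classes", path)
    for i, dom in enumerate(partner.domains):
        dpath = f"{path}/domain[{i}]"
        if not dom.name:
            c.add("MISSING_MANDATORY", "error", dpath, "domain name is empty")
        c.vocab(dom.status, "domain_statuses", dpath)


def _check_junction(c: _Collector, junction: model.SpliceJunction, path: str) -> None:
    from . import fusion_semantics

    for label, dinucleotide in (
        ("donor", junction.donor_dinucleotide),
        ("acceptor", junction.acceptor_dinucleotide),
    ):
        if dinucleotide is not None and not _DINUCLEOTIDE.match(dinucleotide):
            c.add(
                "PATTERN_MISMATCH",
                "error",
                path,
                f"{label} dinucleotide {dinucleotide!r} is not two of ACGT",
            )
    c.vocab(junction.pattern, "splice_patterns", path)
    if (
        junction.donor_dinucleotide
        and junction.acceptor_dinucleotide
        and _DINUCLEOTIDE.match(junction.donor_dinucleotide)
        and _DINUCLEOTIDE.match(junction.acceptor_dinucleotide)
        and junction.pattern in ("canonical", "non_canonical")
    ):
        expected = fusion_semantics.classify_splice_pattern(
            junction.donor_dinucleotide, junction.acceptor_dinucleotide
        )
        if expected != junction.pattern:
            c.add(
                "PATTERN_MISMATCH",
                "error",
                path,
                f"pattern {junction.pattern!r} contradicts dinucleotides "
                f"{junction.donor_dinucleotide}-{junction.acceptor_dinucleotide} "
                f"({expected})",
            )


def _check_evidence(c: _Collector, ev: model.ReadEvidence, path: str) -> None:
    for name in ("junction_read_count", "spanning_pair_count", "unique_read_count"):
        value = getattr(ev, name)
        if value is not None and value < 0:
            c.add("COORD_INVALID", "error", path, f"{name} {value} is negative")
    if ev.rpkm is not None and ev.rpkm < 0:
        c.add("COORD_INVALID", "error", path, f"rpkm {ev.rpkm} is negative")
    for read_id, seq in ev.reads:
        if not _READ_SEQ.match(seq or ""):
            c.add(
                "PATTERN_MISMATCH",
                "error",
                f"{path}/read[{read_id}]",
                f"read sequence is not [ACGTN]+: {seq!r:.40}",
            )


def _check_record(c: _Collector, record: Record) -> None:
    rid = record.id or "?"
    for attr, label in CATEGORIES:
        if label in MANDATORY_CATEGORIES and not getattr(record, attr):
            c.add(
                "MISSING_MANDATORY",
                "error",
                f"{rid}/{label}",
                f"mandatory element category {label!r} is missing or empty",
            )
    seen: dict[str, str] = {}
    for label, el in record.elements():
        if el.id in seen:
            c.add(
                "DUPLICATE_ID",
                "error",
                f"{rid}/{label}[{el.id}]",
                f"identifier {el.id!r} already used by a {seen[el.id]} element",
            )
        else:
            seen[el.id] = label

    for src in record.sources:
        path = f"{rid}/source[{src.id}]"
        c.vocab(src.source_type, "source_types", path)
        if src.source_type == "publication" and not (src.pubmed_id or src.title):
            c.add(
                "MISSING_MANDATORY",
                "error",
                path,
                "publication source needs a pubmed_id or a title",
            )
        if src.year is not None and not (1800 <= src.year <= 2200):
            c.add("COORD_INVALID", "warning", path, f"implausible year {src.year}")
    for sample in record.samples:
        path = f"{rid}/sample[{sample.id}]"
        if not sample.organism:
            c.add("MISSING_MANDATORY", "error", path, "sample organism is empty")
        if not sample.tissue_type:
            c.add("MISSING_MANDATORY", "error", path, "sample tissue_type is empty")
        c.vocab(sample.sample_class, "sample_classes", path)
    for platform in record.sequence_platforms:
        path = f"{rid}/sequence_platform[{platform.id}]"
        if not platform.name:
            c.add("MISSING_MANDATORY", "error", path, "platform name is empty")
        c.vocab(platform.application_type, "platform_applications", path)
    for platform in record.validation_platforms:
        c.vocab(
            platform.method,
            "validation_methods",
            f"{rid}/validation_platform[{platform.id}]",
        )
    for algo in record.mapping_algorithms:
        if not algo.name:
            c.add(
                "MISSING_MANDATORY",
                "error",
                f"{rid}/mapping_algorithm[{algo.id}]",
                "algorithm name is empty",
            )
    for algo in record.fusion_detection_algorithms:
        if not algo.name:
            c.add(
                "MISSING_MANDATORY",
                "error",
                f"{rid}/fusion_detection_algorithm[{algo.id}]",
                "algorithm name is empty",
            )
    for repo in record.sequence_repositories:
        if not (repo.accession or repo.uri):
            c.add(
                "MISSING_MANDATORY",
                "error",
                f"{rid}/sequence_repository[{repo.id}]",
                "repository needs an accession or a uri",
            )

    ids = {el.id for _, el in record.elements()}
    for fusion in record.gene_fusions:
        fpath = f"{rid}/gene_fusion[{fusion.id}]"
        if not fusion.sample_ref:
            c.add("MISSING_MANDATORY", "error", fpath, "sample_ref is missing")
        for name, target in fusion.refs():
            if target not in ids:
                c.add(
                    "DANGLING_REF",
                    "error",
                    f"{fpath}/{name}",
                    f"{name} points at {target!r}, absent from record {rid!r}",
                )
        for role, partner in (
            ("five_prime", fusion.five_prime),
            ("three_prime", fusion.three_prime),
        ):
            if partner is None:
                c.add("MISSING_MANDATORY", "error", f"{fpath}/{role}", "partner missing")
                continue
            if partner.role != role:
                c.add(
                    "VOCAB_VIOLATION",
                    "error",
                    f"{fpath}/{role}",
                    f"partner in {role} position declares role {partner.role!r}",
                )
            _check_partner(c, partner, f"{fpath}/{role}")
        if fusion.junction is not None:
            _check_junction(c, fusion.junction, f"{fpath}/junction")
        if fusion.evidence is not None:
            _check_evidence(c, fusion.evidence, f"{fpath}/evidence")
        c.vocab(fusion.orf_status, "orf_statuses", fpath)
        c.vocab(fusion.mechanism, "mechanisms", fpath)
        c.vocab(fusion.product_class, "product_classes", fpath)
        for i, v in enumerate(fusion.validations):
            vpath = f"{fpath}/validation[{i}]"
            c.vocab(v.outcome, "validation_outcomes", vpath)
            if v.outcome != "untested" and not v.platform_ref:
                c.add(
                    "DANGLING_REF",
                    "error",
                    vpath,
                    f"outcome {v.outcome!r} requires a resolvable platform_ref",
                )


def validate(
    record_set: RecordSet,
    strict: bool = False,
    registry: Optional[VocabularyRegistry] = None,
) -> ValidationReport:
    """Validate a record set; all problems become findings, never exceptions.

    Parameters
    ----------
    record_set
        The set to check; may have been built leniently from a deficient
        document.
    strict
        Promote vocabulary violations from warnings to errors.
    registry
        Vocabulary registry to check terms against; defaults to the
        built-in one.

    Returns
    -------
    ValidationReport
        Findings sorted by path, code and message; ``is_valid`` is true
        iff no error-severity finding exists.
    """
    c = _Collector(strict=strict, registry=registry or DEFAULT_REGISTRY)
    if not record_set.records:
        c.add(
            "MISSING_MANDATORY",
            "error",
            "/",
            "record set must contain at least one record",
        )
    seen: set[str] = set()
    for record in record_set.records:
        if record.id in seen:
            c.add(
                "DUPLICATE_ID",
                "error",
                f"{record.id}",
                f"record id {record.id!r} occurs more than once in the set",
            )
        seen.add(record.id)
        _check_record(c, record)
    return ValidationReport(c.findings).sorted()
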