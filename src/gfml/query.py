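"""Composable queries over record sets.

A :class:`Predicate` is either an atom — a registered field selector, an
operator and a value — or a combinator (``all_of`` / ``any_of`` /
``not``) over child predicates.  Atoms are evaluated per fusion with
cross-reference resolution: selectors like ``sample.tissue_type`` or
``validation.platform.method`` follow the fusion's reference attributes
to the elements of the enclosing record.  A fusion whose evaluation hits
a dangling reference is excluded from the result and reported as a
warning.

Matching semantics: ``equals`` is case-insensitive exact (numeric when
both sides parse as numbers), ``contains`` is case-insensitive
substring, ``ge``/``le`` are numeric, ``exists`` tests presence, and
``in_set`` is case-insensitive membership.  Absent optional fields never
match except through ``exists false``.

Queries compile from a small textual language (``field op value`` with
``and`` / ``or`` / ``not`` and parentheses) or from an equivalent JSON
structure; :func:`table1_suite` prebuilds the catalogue of seventeen
biologically motivated queries spanning clinical, molecular-biology and
bioinformatic use.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

from .model import GeneFusion, GfmlError, Record, RecordSet, resolve_reference
from .validation import _edit_distance

__all__ = [
    "Predicate",
    "Atom",
    "AllOf",
    "AnyOf",
    "Not",
    "QueryResult",
    "QueryError",
    "SELECTORS",
    "OPERATORS",
    "compile_query",
    "run_query",
    "table1_suite",
]


class QueryError(GfmlError):
    """A query uses an unknown selector/operator or cannot be parsed."""


class _DanglingRef(Exception):
    def __init__(self, detail: str):
        self.detail = detail


def _resolve(record: Record, ref: Optional[str], what: str):
    if not ref:
        return None
    element = resolve_reference(record, ref)
    if element is None:
        raise _DanglingRef(f"{what} reference {ref!r} does not resolve")
    return element


def _sel_gene_symbol(f: GeneFusion, r: Record) -> list:
    return [f.five_prime.gene_symbol, f.three_prime.gene_symbol]


def _sel_sample(attr: str) -> Callable[[GeneFusion, Record], list]:
    def select(f: GeneFusion, r: Record) -> list:
        sample = _resolve(r, f.sample_ref, "sample")
        value = getattr(sample, attr, None) if sample is not None else None
        return [value] if value else []

    return select


def _sel_domains(f: GeneFusion, r: Record):
    for partner in (f.five_prime, f.three_prime):
        for dom in partner.domains:
            yield partner, dom


#: selector name -> (extractor(fusion, record) -> list of values, doc)
SELECTORS: dict[str, tuple[Callable[[GeneFusion, Record], list], str]] = {}


def _selector(name: str, doc: str):
    def register(fn):
        SELECTORS[name] = (fn, doc)
        return fn

    return register


_selector("gene_symbol", "symbol of either partner")(_sel_gene_symbol)
_selector("five_prime.gene_symbol", "5' partner symbol")(
    lambda f, r: [f.five_prime.gene_symbol]
)
_selector("three_prime.gene_symbol", "3' partner symbol")(
    lambda f, r: [f.three_prime.gene_symbol]
)
_selector("sample.tissue_type", "tissue of the referenced sample")(
    _sel_sample("tissue_type")
)
_selector("sample.disease", "disease annotation of the referenced sample")(
    _sel_sample("disease")
)
_selector("sample.organism", "organism of the referenced sample")(
    _sel_sample("organism")
)
_selector("sample.sample_class", "specimen class of the referenced sample")(
    _sel_sample("sample_class")
)
_selector("source.pubmed_id", "PubMed ids of the record's sources")(
    lambda f, r: [s.pubmed_id for s in r.sources if s.pubmed_id]
)
_selector("source.author", "author names over the record's sources")(
    lambda f, r: [a for s in r.sources for a in s.authors]
)
_selector("domain.name", "names of annotated domains on either partner")(
    lambda f, r: [d.name for _, d in _sel_domains(f, r)]
)
_selector("domain.status", "retained/broken/lost status of any domain")(
    lambda f, r: [d.status for _, d in _sel_domains(f, r)]
)
_selector("domain.partner_role", "role of each partner carrying a domain")(
    lambda f, r: [p.role for p, _ in _sel_domains(f, r)]
)
_selector("domain.broken_name", "names of domains with broken/lost status")(
    lambda f, r: [d.name for _, d in _sel_domains(f, r) if d.status in ("broken", "lost")]
)
_selector("five_prime.domain.name", "domain names on the 5' partner")(
    lambda f, r: [d.name for d in f.five_prime.domains]
)
_selector("three_prime.domain.name", "domain names on the 3' partner")(
    lambda f, r: [d.name for d in f.three_prime.domains]
)
_selector("orf_status", "reading-frame status")(lambda f, r: [f.orf_status])
_selector("product_class", "fusion-product class")(lambda f, r: [f.product_class])
_selector("mechanism", "inferred rearrangement mechanism")(lambda f, r: [f.mechanism])
_selector("junction.pattern", "splice-pattern class of the junction")(
    lambda f, r: [f.junction.pattern] if f.junction else []
)
_selector("partner.boundary_class", "boundary class of either partner")(
    lambda f, r: [f.five_prime.boundary_class, f.three_prime.boundary_class]
)
_selector("five_prime.boundary_class", "boundary class of the 5' partner")(
    lambda f, r: [f.five_prime.boundary_class]
)
_selector("three_prime.boundary_class", "boundary class of the 3' partner")(
    lambda f, r: [f.three_prime.boundary_class]
)


@_selector("validation.platform.method", "method of each validation's platform")
def _sel_validation_method(f: GeneFusion, r: Record) -> list:
    methods = []
    for v in f.validations:
        platform = _resolve(r, v.platform_ref, "validation platform")
        if platform is not None:
            methods.append(getattr(platform, "method", None))
    return [m for m in methods if m]


_selector("validation.outcome", "outcome of any validation attempt")(
    lambda f, r: [v.outcome for v in f.validations]
)


@_selector("platform.name", "name of the referenced sequencing platform")
def _sel_platform_name(f: GeneFusion, r: Record) -> list:
    platform = _resolve(r, f.sequence_platform_ref, "sequencing platform")
    name = getattr(platform, "name", None) if platform is not None else None
    return [name] if name else []


@_selector("mapping_algorithm.name", "name of the referenced mapping algorithm")
def _sel_mapping_name(f: GeneFusion, r: Record) -> list:
    algo = _resolve(r, f.mapping_algorithm_ref, "mapping algorithm")
    name = getattr(algo, "name", None) if algo is not None else None
    return [name] if name else []


@_selector(
    "fusion_detection_algorithm.name",
    "name of the referenced fusion-detection algorithm",
)
def _sel_fusion_algo_name(f: GeneFusion, r: Record) -> list:
    algo = _resolve(r, f.fusion_detection_algorithm_ref, "fusion-detection algorithm")
    name = getattr(algo, "name", None) if algo is not None else None
    return [name] if name else []


_selector("evidence.present", "whether read evidence is attached")(
    lambda f, r: [True] if f.evidence is not None else []
)
_selector("evidence.reads", "number of stored read sequences")(
    lambda f, r: [len(f.evidence.reads)] if f.evidence is not None else []
)
_selector("evidence.rpkm", "expression of the fusion transcript (RPKM)")(
    lambda f, r: [f.evidence.rpkm] if f.evidence and f.evidence.rpkm is not None else []
)
_selector("evidence.unique_read_count", "unique supporting reads")(
    lambda f, r: [f.evidence.unique_read_count]
    if f.evidence and f.evidence.unique_read_count is not None
    else []
)
_selector("evidence.junction_read_count", "reads crossing the junction")(
    lambda f, r: [f.evidence.junction_read_count] if f.evidence else []
)

OPERATORS = ("equals", "contains", "ge", "le", "exists", "in_set")


def _as_number(value) -> Optional[float]:
    if isinstance(value, bool):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def _truthy(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("true", "1", "yes")


@dataclass(frozen=True)
class Atom:
    field_path: str
    operator: str
    value: object = None

    def __post_init__(self):
        if self.field_path not in SELECTORS:
            suggestion = min(
                sorted(SELECTORS),
                key=lambda s: _edit_distance(self.field_path.lower(), s.lower()),
            )
            raise QueryError(
                f"unknown selector {self.field_path!r} "
                f"(did you mean {suggestion!r}?); "
                f"valid selectors: {', '.join(sorted(SELECTORS))}"
            )
        if self.operator not in OPERATORS:
            raise QueryError(
                f"unknown operator {self.operator!r}; "
                f"valid operators: {', '.join(OPERATORS)}"
            )
        if self.operator in ("ge", "le"):
            number = _as_number(self.value)
            if number is None:
                raise QueryError(
                    f"operator {self.operator!r} needs a numeric value, "
                    f"got {self.value!r}"
                )
            object.__setattr__(self, "value", number)

    def matches(self, fusion: GeneFusion, record: Record) -> bool:
        values = list(SELECTORS[self.field_path][0](fusion, record))
        if self.operator == "exists":
            want = True if self.value is None else _truthy(self.value)
            return bool(values) == want
        for v in values:
            if v is None:
                continue
            if self.operator == "equals":
                number, target = _as_number(v), _as_number(self.value)
                if number is not None and target is not None:
                    if number == target:
                        return True
                elif str(v).lower() == str(self.value).lower():
                    return True
            elif self.operator == "contains":
                if str(self.value).lower() in str(v).lower():
                    return True
            elif self.operator in ("ge", "le"):
                number, target = _as_number(v), _as_number(self.value)
                if number is None or target is None:
                    continue
                if (number >= target) if self.operator == "ge" else (number <= target):
                    return True
            elif self.operator == "in_set":
                members = (
                    self.value
                    if isinstance(self.value, (list, tuple, set, frozenset))
                    else re.split(r"[,\s]+", str(self.value).strip("[]{}"))
                )
                if str(v).lower() in {str(m).lower() for m in members if str(m)}:
                    return True
        return False

    def to_dict(self) -> dict:
        value = (
            sorted(self.value) if isinstance(self.value, frozenset) else self.value
        )
        return {"field": self.field_path, "op": self.operator, "value": value}


@dataclass(frozen=True)
class AllOf:
    children: tuple

    def matches(self, fusion: GeneFusion, record: Record) -> bool:
        return all(c.matches(fusion, record) for c in self.children)

    def to_dict(self) -> dict:
        return {"all_of": [c.to_dict() for c in self.children]}


@dataclass(frozen=True)
class AnyOf:
    children: tuple

    def matches(self, fusion: GeneFusion, record: Record) -> bool:
        return any(c.matches(fusion, record) for c in self.children)

    def to_dict(self) -> dict:
        return {"any_of": [c.to_dict() for c in self.children]}


@dataclass(frozen=True)
class Not:
    child: "Predicate"

    def matches(self, fusion: GeneFusion, record: Record) -> bool:
        return not self.child.matches(fusion, record)

    def to_dict(self) -> dict:
        return {"not": self.child.to_dict()}


Predicate = Union[Atom, AllOf, AnyOf, Not]


def all_of(*children: Predicate) -> AllOf:
    return AllOf(tuple(children))


def any_of(*children: Predicate) -> AnyOf:
    return AnyOf(tuple(children))


def not_(child: Predicate) -> Not:
    return Not(child)


@dataclass
class QueryResult:
    matches: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.matches)


def run_query(record_set: RecordSet, predicate: Predicate) -> QueryResult:
    """Evaluate a predicate over every fusion of every record.

    Result order is deterministic: record order, then fusion order.  A
    fusion whose evaluation encounters a dangling reference is excluded
    with a warning rather than failing the query.
    """
    result = QueryResult()
    for record in record_set.records:
        for fusion in record.gene_fusions:
            try:
                if predicate.matches(fusion, record):
                    result.matches.append((record.id, fusion.id))
            except _DanglingRef as exc:
                result.warnings.append(
                    f"{record.id}/{fusion.id} excluded: {exc.detail}"
                )
    return result


# ---------------------------------------------------------------------------
# compilation

_TOKEN = re.compile(
    r"""\s*(?:(?P<lparen>\()|(?P<rparen>\))|(?P<quoted>"[^"]*")|(?P<word>[^\s()]+))"""
)


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            break
        pos = m.end()
        tokens.append(m.group("lparen") or m.group("rparen") or m.group("quoted") or m.group("word"))
    return tokens


class _Parser:
    """Recursive descent over: expr := term ('or' term)*;
    term := factor ('and' factor)*; factor := 'not' factor | '(' expr ')' | atom."""

    def __init__(self, tokens: list[str], source: str):
        self.tokens = tokens
        self.pos = 0
        self.source = source

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        token = self.peek()
        if token is None:
            raise QueryError(f"unexpected end of query: {self.source!r}")
        self.pos += 1
        return token

    def expr(self) -> Predicate:
        terms = [self.term()]
        while self.peek() and self.peek().lower() == "or":
            self.take()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else AnyOf(tuple(terms))

    def term(self) -> Predicate:
        factors = [self.factor()]
        while self.peek() and self.peek().lower() == "and":
            self.take()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else AllOf(tuple(factors))

    def factor(self) -> Predicate:
        token = self.peek()
        if token is None:
            raise QueryError(f"unexpected end of query: {self.source!r}")
        if token.lower() == "not":
            self.take()
            return Not(self.factor())
        if token == "(":
            self.take()
            inner = self.expr()
            if self.take() != ")":
                raise QueryError(f"expected ')' in query {self.source!r}")
            return inner
        return self.atom()

    def atom(self) -> Atom:
        selector = self.take()
        operator = self.take().lower()
        if operator == "exists":
            value = None
            nxt = self.peek()
            if nxt and nxt.lower() in ("true", "false"):
                value = self.take().lower() == "true"
        else:
            value = self.take()
            if value.startswith('"') and value.endswith('"'):
                value = value[1:-1]
        return Atom(selector, operator, value)


def _from_structured(spec: dict) -> Predicate:
    if "all_of" in spec:
        return AllOf(tuple(_from_structured(c) for c in spec["all_of"]))
    if "any_of" in spec:
        return AnyOf(tuple(_from_structured(c) for c in spec["any_of"]))
    if "not" in spec:
        return Not(_from_structured(spec["not"]))
    if "field" in spec and "op" in spec:
        return Atom(spec["field"], spec["op"], spec.get("value"))
    raise QueryError(
        f"structured query node must carry all_of/any_of/not or field+op: {spec!r}"
    )


def compile_query(spec: Union[str, dict]) -> Predicate:
    """Compile a textual or structured query description into a predicate.

    Textual form: ``field op value`` atoms combined with ``and``, ``or``,
    ``not`` and parentheses; values with spaces are double-quoted.  A
    JSON object (or JSON text) with ``field``/``op``/``value`` atoms and
    ``all_of``/``any_of``/``not`` combinators is accepted equivalently.
    """
    if isinstance(spec, dict):
        return _from_structured(spec)
    text = spec.strip()
    if text.startswith("{"):
        try:
            return _from_structured(json.loads(text))
        except json.JSONDecodeError as exc:
            raise QueryError(f"invalid JSON query: {exc}") from exc
    tokens = _tokenize(text)
    if not tokens:
        raise QueryError("empty query")
    parser = _Parser(tokens, text)
    predicate = parser.expr()
    if parser.peek() is not None:
        raise QueryError(
            f"trailing tokens {parser.tokens[parser.pos:]} in query {text!r}"
        )
    return predicate


# ---------------------------------------------------------------------------
# the seventeen-query catalogue

def table1_suite(
    gene: str = "ERG",
    tissue: str = "prostate",
    disease: str = "leiomyosarcoma",
    reference: Optional[str] = None,
    domain: str = "kinase",
    break_domains: tuple[str, ...] = ("SH2", "SH3"),
    validation_method: str = "FISH",
    sequencing_platform: str = "Illumina",
    mapping_algorithm: str = "Bowtie",
    fusion_algorithm: str = "ShortFuse",
    rpkm_threshold: float = 50.0,
) -> dict[str, Predicate]:
    """The catalogue of seventeen prebuilt queries, in presentation order.

    Rows that imply a parameter (gene, tissue, disease, domain name,
    platform, threshold) take it as an argument; the defaults reproduce
    the catalogue's illustrative examples (fusions involving ERG,
    prostate tissue, validation by FISH, candidates above 50 RPKM, ...).
    """
    reference_predicate: Predicate
    if reference is None:
        reference_predicate = Atom("source.pubmed_id", "exists", True)
    elif reference.isdigit():
        reference_predicate = Atom("source.pubmed_id", "equals", reference)
    else:
        reference_predicate = Atom("source.author", "contains", reference)
    return {
        # clinicians
        "gene_identifier": Atom("gene_symbol", "equals", gene),
        "sample_type": Atom("sample.tissue_type", "equals", tissue),
        "clinical_significance": Atom("sample.disease", "contains", disease),
        "reference": reference_predicate,
        # molecular biologists
        "protein_domain": Atom("domain.name", "contains", domain),
        "domain_break": AnyOf(
            tuple(Atom("domain.broken_name", "equals", d) for d in break_domains)
        ),
        "domain_region": Atom("three_prime.domain.name", "contains", domain),
        "orf_status": Atom("orf_status", "equals", "in_frame"),
        "validation_platform": Atom(
            "validation.platform.method", "equals", validation_method
        ),
        "splice_pattern": Atom("junction.pattern", "equals", "non_canonical"),
        "fusion_product": Atom(
            "product_class", "in_set", ("fusion_protein", "truncated_protein")
        ),
        "fusion_mechanism": Atom("mechanism", "equals", "inversion"),
        "splice_boundary": Atom("five_prime.boundary_class", "equals", "intergenic"),
        # bioinformaticians
        "sequencing_platform": Atom("platform.name", "contains", sequencing_platform),
        "sequence_evidence": Atom("evidence.reads", "ge", 1),
        "algorithm": AllOf(
            (
                Atom("mapping_algorithm.name", "equals", mapping_algorithm),
                Atom("fusion_detection_algorithm.name", "equals", fusion_algorithm),
            )
        ),
        "rpkm_unique_count": Atom("evidence.rpkm", "ge", rpkm_threshold),
    }
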