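"""Reading and writing GFML documents, schema export, tabular import and
BEDPE export.

The document layout follows the nine-category record structure: the root
``Record_Set`` holds one or more ``Record`` elements, each carrying the
``*_List`` category elements in a fixed order.  Identifiers and
references are XML attributes; descriptive scalars are child elements.
Serialisation is deterministic — fixed element and attribute order,
UTF-8, pretty-printed — so writing is a fixpoint after one round-trip.

Reading is strict by default (a structurally deficient document is
refused, with the validation report attached to the exception) and
lenient on request, in which case the document is materialised as far as
possible and every problem is attached as a finding.  Unknown elements
are preserved verbatim and reported with a warning rather than dropped.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field, fields as dataclass_fields
from typing import Optional

from lxml import etree

from . import model
from .model import GfmlError, Record, RecordSet
from .validation import (
    ValidationFinding,
    ValidationReport,
    VocabularyRegistry,
    validate,
)

__all__ = [
    "GfmlParseError",
    "GfmlFormatError",
    "ColumnMap",
    "RowError",
    "STRUCTURAL_CODES",
    "write_gfml",
    "read_gfml",
    "validate_document",
    "export_schema",
    "import_fusion_table",
    "export_bedpe",
]


class GfmlParseError(GfmlError):
    """The input is not well-formed XML."""

    def __init__(self, message: str, line: Optional[int] = None, column: Optional[int] = None):
        self.line = line
        self.column = column
        where = f" (line {line}, column {column})" if line is not None else ""
        super().__init__(f"{message}{where}")


class GfmlFormatError(GfmlError):
    """Well-formed XML that is not an acceptable GFML document."""

    def __init__(self, message: str, report: Optional[ValidationReport] = None):
        self.report = report
        super().__init__(message)


#: Finding codes whose error-level presence the exported schema also
#: expresses (cardinality, identifier uniqueness, reference resolution,
#: coordinate/strand value spaces).  Vocabulary terms and cross-field
#: consistency stay outside the schema to keep the format flexible.
STRUCTURAL_CODES = frozenset(
    {
        "MISSING_MANDATORY",
        "EMPTY_LIST",
        "DUPLICATE_ID",
        "DANGLING_REF",
        "COORD_INVALID",
        "STRAND_INVALID",
    }
)

_LIST_NAMES: tuple[tuple[str, str, str], ...] = (
    # (record attribute, list element name, item element name)
    ("sources", "Source_List", "Source"),
    ("samples", "Sample_List", "Sample"),
    ("experiments", "Experiment_List", "Experiment"),
    ("sequence_platforms", "Sequence_Platform_List", "Sequence_Platform"),
    ("validation_platforms", "Validation_Platform_List", "Validation_Platform"),
    ("mapping_algorithms", "Mapping_Algorithm_List", "Mapping_Algorithm"),
    (
        "fusion_detection_algorithms",
        "Fusion_Detection_Algorithm_List",
        "Fusion_Detection_Algorithm",
    ),
    ("sequence_repositories", "Sequence_Repository_List", "Sequence_Repository"),
    ("gene_fusions", "Gene_Fusion_List", "Gene_Fusion"),
)

_KNOWN_RECORD_CHILDREN = {name for _, name, _ in _LIST_NAMES}


# ---------------------------------------------------------------------------
# writing

def _scalar(parent: etree._Element, name: str, value) -> None:
    if value is None:
        return
    child = etree.SubElement(parent, name)
    if isinstance(value, float):
        child.text = repr(value)
    else:
        child.text = str(value)


def _parameters(parent: etree._Element, params: list[tuple[str, str]]) -> None:
    for name, value in params:
        p = etree.SubElement(parent, "Parameter")
        _scalar(p, "Name", name)
        _scalar(p, "Value", value)


def _partner_element(parent: etree._Element, name: str, p: model.FusionPartner) -> None:
    el = etree.SubElement(parent, name)
    _scalar(el, "Gene_Symbol", p.gene_symbol)
    if p.gene_accession is not None:
        acc = etree.SubElement(el, "Gene_Accession")
        acc.set("namespace", p.gene_accession[0])
        acc.text = p.gene_accession[1]
    _scalar(el, "Chromosome", p.chromosome)
    _scalar(el, "Strand", p.strand)
    _scalar(el, "Breakpoint", p.breakpoint)
    _scalar(el, "Transcript_Accession", p.transcript_accession)
    _scalar(el, "Exon_Number", p.exon_number)
    _scalar(el, "Boundary_Class", p.boundary_class)
    for dom in p.domains:
        d = etree.SubElement(el, "Domain")
        if dom.accession is not None:
            d.set("accession", dom.accession)
        _scalar(d, "Name", dom.name)
        _scalar(d, "Status", dom.status)


def _fusion_element(parent: etree._Element, f: model.GeneFusion) -> None:
    el = etree.SubElement(parent, "Gene_Fusion")
    el.set("id", f.id)
    el.set("sample_ref", f.sample_ref)
    for attr in (
        "experiment_ref",
        "mapping_algorithm_ref",
        "fusion_detection_algorithm_ref",
        "sequence_platform_ref",
    ):
        value = getattr(f, attr)
        if value is not None:
            el.set(attr, value)
    _partner_element(el, "Five_Prime_Partner", f.five_prime)
    _partner_element(el, "Three_Prime_Partner", f.three_prime)
    if f.junction is not None:
        j = etree.SubElement(el, "Splice_Junction")
        _scalar(j, "Donor_Dinucleotide", f.junction.donor_dinucleotide)
        _scalar(j, "Acceptor_Dinucleotide", f.junction.acceptor_dinucleotide)
        _scalar(j, "Pattern", f.junction.pattern)
        _scalar(j, "Junction_Sequence", f.junction.junction_sequence)
    if f.evidence is not None:
        ev = etree.SubElement(el, "Read_Evidence")
        _scalar(ev, "Junction_Read_Count", f.evidence.junction_read_count)
        _scalar(ev, "Spanning_Pair_Count", f.evidence.spanning_pair_count)
        _scalar(ev, "Rpkm", f.evidence.rpkm)
        _scalar(ev, "Unique_Read_Count", f.evidence.unique_read_count)
        for read_id, seq in f.evidence.reads:
            r = etree.SubElement(ev, "Read")
            r.set("id", read_id)
            r.text = seq
    _scalar(el, "Orf_Status", f.orf_status)
    _scalar(el, "Mechanism", f.mechanism)
    _scalar(el, "Product_Class", f.product_class)
    for v in f.validations:
        vel = etree.SubElement(el, "Validation")
        if v.platform_ref is not None:
            vel.set("platform_ref", v.platform_ref)
        _scalar(vel, "Outcome", v.outcome)
        _scalar(vel, "Note", v.note)


def _item_element(parent: etree._Element, item_name: str, item) -> None:
    if isinstance(item, model.GeneFusion):
        _fusion_element(parent, item)
        return
    el = etree.SubElement(parent, item_name)
    el.set("id", item.id)
    if isinstance(item, model.SourceInfo):
        _scalar(el, "Source_Type", item.source_type)
        _scalar(el, "Pubmed_Id", item.pubmed_id)
        _scalar(el, "Title", item.title)
        for author in item.authors:
            _scalar(el, "Author", author)
        _scalar(el, "Year", item.year)
        _scalar(el, "Contact", item.contact)
    elif isinstance(item, model.SampleInfo):
        _scalar(el, "Organism", item.organism)
        _scalar(el, "Tissue_Type", item.tissue_type)
        _scalar(el, "Disease", item.disease)
        _scalar(el, "Sample_Class", item.sample_class)
        _scalar(el, "Description", item.description)
    elif isinstance(item, model.ExperimentInfo):
        _scalar(el, "Title", item.title)
        _scalar(el, "Design_Description", item.design_description)
        _parameters(el, item.parameters)
    elif isinstance(item, model.SequencePlatform):
        _scalar(el, "Name", item.name)
        _scalar(el, "Description", item.description)
        _scalar(el, "Application_Type", item.application_type)
    elif isinstance(item, model.ValidationPlatform):
        _scalar(el, "Method", item.method)
        _scalar(el, "Description", item.description)
    elif isinstance(item, (model.MappingAlgorithm, model.FusionDetectionAlgorithm)):
        _scalar(el, "Name", item.name)
        _scalar(el, "Version", item.version)
        _parameters(el, item.parameters)
    elif isinstance(item, model.SequenceRepository):
        _scalar(el, "Name", item.name)
        _scalar(el, "Accession", item.accession)
        _scalar(el, "Uri", item.uri)
    else:  # pragma: no cover - closed type union
        raise GfmlError(f"unserialisable element type {type(item).__name__}")


def write_gfml(record_set: RecordSet, check: bool = True) -> str:
    """Serialise a record set to GFML document text.

    With ``check`` (the default) the set is validated first and an invalid
    set is refused with the report attached; pass ``check=False`` to
    serialise regardless (used for deliberately defective fixtures).
    """
    if check:
        report = validate(record_set)
        if not report.is_valid:
            raise GfmlFormatError(
                "refusing to write an invalid record set:\n" + report.to_text(),
                report=report,
            )
    root = etree.Element("Record_Set")
    root.set("format_version", record_set.format_version)
    for record in record_set.records:
        rel = etree.SubElement(root, "Record")
        rel.set("id", record.id)
        for attr, list_name, item_name in _LIST_NAMES:
            items = getattr(record, attr)
            if not items:
                continue  # optional categories are absent, never empty
            lel = etree.SubElement(rel, list_name)
            for item in items:
                _item_element(lel, item_name, item)
        for chunk in getattr(record, "extra_xml", ()):  # preserved foreign elements
            rel.append(etree.fromstring(chunk))
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


# ---------------------------------------------------------------------------
# reading

class _Reader:
    def __init__(self) -> None:
        self.findings: list[ValidationFinding] = []

    def warn(self, code: str, path: str, message: str) -> None:
        self.findings.append(ValidationFinding(code, "warning", path, message))

    def error(self, code: str, path: str, message: str) -> None:
        self.findings.append(ValidationFinding(code, "error", path, message))

    def text(self, el: etree._Element, name: str) -> Optional[str]:
        child = el.find(name)
        if child is None:
            return None
        return child.text or ""

    def int_(self, el: etree._Element, name: str, path: str) -> Optional[int]:
        raw = self.text(el, name)
        if raw is None:
            return None
        try:
            return int(raw)
        except ValueError:
            self.error("COORD_INVALID", path, f"{name} {raw!r} is not an integer")
            return None

    def float_(self, el: etree._Element, name: str, path: str) -> Optional[float]:
        raw = self.text(el, name)
        if raw is None:
            return None
        try:
            return float(raw)
        except ValueError:
            self.error("COORD_INVALID", path, f"{name} {raw!r} is not a number")
            return None

    def parameters(self, el: etree._Element) -> list[tuple[str, str]]:
        return [
            (p.findtext("Name") or "", p.findtext("Value") or "")
            for p in el.findall("Parameter")
        ]

    def partner(self, el: Optional[etree._Element], role: str, path: str) -> model.FusionPartner:
        if el is None:
            self.error("MISSING_MANDATORY", path, f"{role} partner element missing")
            return model.FusionPartner(
                role=role, gene_symbol="", chromosome="", strand="", breakpoint=0
            )
        accession = None
        acc_el = el.find("Gene_Accession")
        if acc_el is not None:
            accession = (acc_el.get("namespace", ""), acc_el.text or "")
        return model.FusionPartner(
            role=role,
            gene_symbol=self.text(el, "Gene_Symbol") or "",
            gene_accession=accession,
            chromosome=self.text(el, "Chromosome") or "",
            strand=self.text(el, "Strand") or "",
            breakpoint=self.int_(el, "Breakpoint", path),
            transcript_accession=self.text(el, "Transcript_Accession"),
            exon_number=self.int_(el, "Exon_Number", path),
            boundary_class=self.text(el, "Boundary_Class") or "unknown",
            domains=[
                model.DomainAnnotation(
                    name=self.text(d, "Name") or "",
                    accession=d.get("accession"),
                    status=self.text(d, "Status") or "retained",
                )
                for d in el.findall("Domain")
            ],
        )

    def fusion(self, el: etree._Element, path: str) -> model.GeneFusion:
        junction = None
        jel = el.find("Splice_Junction")
        if jel is not None:
            junction = model.SpliceJunction(
                donor_dinucleotide=self.text(jel, "Donor_Dinucleotide"),
                acceptor_dinucleotide=self.text(jel, "Acceptor_Dinucleotide"),
                pattern=self.text(jel, "Pattern") or "unknown",
                junction_sequence=self.text(jel, "Junction_Sequence"),
            )
        evidence = None
        eel = el.find("Read_Evidence")
        if eel is not None:
            evidence = model.ReadEvidence(
                junction_read_count=self.int_(eel, "Junction_Read_Count", path) or 0,
                spanning_pair_count=self.int_(eel, "Spanning_Pair_Count", path) or 0,
                rpkm=self.float_(eel, "Rpkm", path),
                unique_read_count=self.int_(eel, "Unique_Read_Count", path),
                reads=[(r.get("id", ""), r.text or "") for r in eel.findall("Read")],
            )
        return model.GeneFusion(
            id=el.get("id", ""),
            five_prime=self.partner(
                el.find("Five_Prime_Partner"), "five_prime", f"{path}/five_prime"
            ),
            three_prime=self.partner(
                el.find("Three_Prime_Partner"), "three_prime", f"{path}/three_prime"
            ),
            sample_ref=el.get("sample_ref", ""),
            junction=junction,
            evidence=evidence,
            orf_status=self.text(el, "Orf_Status") or "unknown",
            mechanism=self.text(el, "Mechanism") or "unknown",
            product_class=self.text(el, "Product_Class") or "unknown",
            validations=[
                model.ValidationResult(
                    platform_ref=v.get("platform_ref"),
                    outcome=self.text(v, "Outcome") or "untested",
                    note=self.text(v, "Note"),
                )
                for v in el.findall("Validation")
            ],
            experiment_ref=el.get("experiment_ref"),
            mapping_algorithm_ref=el.get("mapping_algorithm_ref"),
            fusion_detection_algorithm_ref=el.get("fusion_detection_algorithm_ref"),
            sequence_platform_ref=el.get("sequence_platform_ref"),
        )

    def item(self, attr: str, el: etree._Element, path: str):
        el_id = el.get("id", "")
        if attr == "sources":
            return model.SourceInfo(
                id=el_id,
                source_type=self.text(el, "Source_Type") or "publication",
                pubmed_id=self.text(el, "Pubmed_Id"),
                title=self.text(el, "Title"),
                authors=[a.text or "" for a in el.findall("Author")],
                year=self.int_(el, "Year", path),
                contact=self.text(el, "Contact"),
            )
        if attr == "samples":
            return model.SampleInfo(
                id=el_id,
                organism=self.text(el, "Organism") or "",
                tissue_type=self.text(el, "Tissue_Type") or "",
                disease=self.text(el, "Disease"),
                sample_class=self.text(el, "Sample_Class") or "tissue",
                description=self.text(el, "Description"),
            )
        if attr == "experiments":
            return model.ExperimentInfo(
                id=el_id,
                title=self.text(el, "Title"),
                design_description=self.text(el, "Design_Description"),
                parameters=self.parameters(el),
            )
        if attr == "sequence_platforms":
            return model.SequencePlatform(
                id=el_id,
                name=self.text(el, "Name") or "",
                description=self.text(el, "Description"),
                application_type=self.text(el, "Application_Type") or "transcriptome",
            )
        if attr == "validation_platforms":
            return model.ValidationPlatform(
                id=el_id,
                method=self.text(el, "Method") or "",
                description=self.text(el, "Description"),
            )
        if attr == "mapping_algorithms":
            return model.MappingAlgorithm(
                id=el_id,
                name=self.text(el, "Name") or "",
                version=self.text(el, "Version"),
                parameters=self.parameters(el),
            )
        if attr == "fusion_detection_algorithms":
            return model.FusionDetectionAlgorithm(
                id=el_id,
                name=self.text(el, "Name") or "",
                version=self.text(el, "Version"),
                parameters=self.parameters(el),
            )
        if attr == "sequence_repositories":
            return model.SequenceRepository(
                id=el_id,
                name=self.text(el, "Name") or "",
                accession=self.text(el, "Accession"),
                uri=self.text(el, "Uri"),
            )
        return self.fusion(el, path)

    def record(self, el: etree._Element) -> Record:
        rid = el.get("id", "")
        record = Record(id=rid)
        by_name = {name: (attr, item) for attr, name, item in _LIST_NAMES}
        for child in el:
            if not isinstance(child.tag, str):
                continue  # comments / processing instructions
            if child.tag not in by_name:
                self.warn(
                    "UNKNOWN_ELEMENT",
                    f"{rid}/{child.tag}",
                    f"unknown element {child.tag!r} preserved but not interpreted",
                )
                record.extra_xml.append(etree.tostring(child).decode("utf-8").strip())
                continue
            attr, item_name = by_name[child.tag]
            items = [
                self.item(attr, item_el, f"{rid}/{child.tag}/{item_el.get('id', '?')}")
                for item_el in child.findall(item_name)
            ]
            if not items:
                self.error(
                    "EMPTY_LIST",
                    f"{rid}/{child.tag}",
                    f"{child.tag} is present but holds no {item_name} element",
                )
            getattr(record, attr).extend(items)
        return record


def _parse(document: str) -> etree._Element:
    try:
        return etree.fromstring(document.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        line, column = (exc.position or (None, None))
        raise GfmlParseError(f"malformed XML: {exc.args[0]}", line, column) from exc


def read_gfml(
    document: str,
    lenient: bool = False,
    registry: Optional[VocabularyRegistry] = None,
):
    """Parse GFML document text.

    In strict mode (default) returns the :class:`RecordSet` and raises
    :class:`GfmlFormatError` if the document has any error-severity
    finding.  In lenient mode returns ``(RecordSet, ValidationReport)``,
    loading deficient documents as far as possible.

    Raises
    ------
    GfmlParseError
        For XML that is not well-formed (with line/column).
    GfmlFormatError
        For a root element other than ``Record_Set``, or — in strict mode
        — for structurally invalid documents.
    """
    root = _parse(document)
    if root.tag != "Record_Set":
        raise GfmlFormatError(
            f"root element is {root.tag!r}, expected 'Record_Set'"
        )
    reader = _Reader()
    records = [
        reader.record(el) for el in root if isinstance(el.tag, str) and el.tag == "Record"
    ]
    for el in root:
        if isinstance(el.tag, str) and el.tag != "Record":
            reader.warn(
                "UNKNOWN_ELEMENT",
                f"/{el.tag}",
                f"unknown element {el.tag!r} under Record_Set ignored",
            )
    record_set = RecordSet(
        records=records,
        format_version=root.get("format_version", "prototype-1"),
    )
    report = ValidationReport(reader.findings).merged(
        validate(record_set, registry=registry)
    )
    if lenient:
        return record_set, report
    if not report.is_valid:
        raise GfmlFormatError(
            "document is not valid GFML:\n" + report.to_text(), report=report
        )
    return record_set


def validate_document(
    document: str,
    strict: bool = False,
    registry: Optional[VocabularyRegistry] = None,
) -> ValidationReport:
    """Lenient parse + validation of document text, returning the merged
    report (parse-level findings such as EMPTY_LIST plus model findings)."""
    root = _parse(document)
    if root.tag != "Record_Set":
        raise GfmlFormatError(f"root element is {root.tag!r}, expected 'Record_Set'")
    reader = _Reader()
    records = [
        reader.record(el) for el in root if isinstance(el.tag, str) and el.tag == "Record"
    ]
    record_set = RecordSet(records=records)
    return ValidationReport(reader.findings).merged(
        validate(record_set, strict=strict, registry=registry)
    )


# ---------------------------------------------------------------------------
# schema export

def export_schema() -> str:
    """Emit an XML Schema Definition for the GFML document structure.

    The schema encodes the structural rules: the three mandatory
    categories have ``minOccurs="1"``, optional categories
    ``minOccurs="0"``, every present category holds one-to-unbounded
    children, identifiers are unique per record (``xs:key``) and every
    reference attribute must resolve (``xs:keyref``).  Vocabulary terms
    are left as free strings: term checking is the validator's job so the
    format stays open to community extension.
    """
    mandatory = {"Source_List", "Sample_List", "Gene_Fusion_List"}

    def list_el(list_name: str, body: str) -> str:
        min_occurs = "1" if list_name in mandatory else "0"
        return (
            f'<xs:element name="{list_name}" minOccurs="{min_occurs}">'
            f"<xs:complexType><xs:sequence>{body}</xs:sequence></xs:complexType>"
            f"</xs:element>"
        )

    def scalar(name: str, type_: str = "xs:string", required: bool = False) -> str:
        min_occurs = "1" if required else "0"
        return f'<xs:element name="{name}" type="{type_}" minOccurs="{min_occurs}"/>'

    parameter = (
        '<xs:element name="Parameter" minOccurs="0" maxOccurs="unbounded">'
        "<xs:complexType><xs:sequence>"
        + scalar("Name", "nonEmptyString", required=True)
        + scalar("Value")
        + "</xs:sequence></xs:complexType></xs:element>"
    )

    def item(name: str, body: str, extra_attrs: str = "") -> str:
        return (
            f'<xs:element name="{name}" maxOccurs="unbounded">'
            f"<xs:complexType><xs:sequence>{body}</xs:sequence>"
            f'<xs:attribute name="id" type="nonEmptyString" use="required"/>'
            f"{extra_attrs}</xs:complexType></xs:element>"
        )

    partner_body = (
        scalar("Gene_Symbol", "nonEmptyString", required=True)
        + '<xs:element name="Gene_Accession" minOccurs="0">'
        "<xs:complexType><xs:simpleContent>"
        '<xs:extension base="xs:string">'
        '<xs:attribute name="namespace" type="xs:string"/>'
        "</xs:extension></xs:simpleContent></xs:complexType></xs:element>"
        + scalar("Chromosome", "nonEmptyString", required=True)
        + scalar("Strand", "strandType", required=True)
        + scalar("Breakpoint", "xs:positiveInteger", required=True)
        + scalar("Transcript_Accession")
        + scalar("Exon_Number", "xs:positiveInteger")
        + scalar("Boundary_Class")
        + '<xs:element name="Domain" minOccurs="0" maxOccurs="unbounded">'
        "<xs:complexType><xs:sequence>"
        + scalar("Name", "nonEmptyString", required=True)
        + scalar("Status")
        + "</xs:sequence>"
        '<xs:attribute name="accession" type="xs:string"/>'
        "</xs:complexType></xs:element>"
    )

    def partner(name: str) -> str:
        return (
            f'<xs:element name="{name}">'
            f"<xs:complexType><xs:sequence>{partner_body}</xs:sequence>"
            f"</xs:complexType></xs:element>"
        )

    fusion_body = (
        partner("Five_Prime_Partner")
        + partner("Three_Prime_Partner")
        + '<xs:element name="Splice_Junction" minOccurs="0">'
        "<xs:complexType><xs:sequence>"
        + scalar("Donor_Dinucleotide", "dinucleotideType")
        + scalar("Acceptor_Dinucleotide", "dinucleotideType")
        + scalar("Pattern")
        + scalar("Junction_Sequence", "readSequenceType")
        + "</xs:sequence></xs:complexType></xs:element>"
        + '<xs:element name="Read_Evidence" minOccurs="0">'
        "<xs:complexType><xs:sequence>"
        + scalar("Junction_Read_Count", "xs:nonNegativeInteger")
        + scalar("Spanning_Pair_Count", "xs:nonNegativeInteger")
        + scalar("Rpkm", "nonNegativeFloat")
        + scalar("Unique_Read_Count", "xs:nonNegativeInteger")
        + '<xs:element name="Read" minOccurs="0" maxOccurs="unbounded">'
        "<xs:complexType><xs:simpleContent>"
        '<xs:extension base="readSequenceType">'
        '<xs:attribute name="id" type="xs:string" use="required"/>'
        "</xs:extension></xs:simpleContent></xs:complexType></xs:element>"
        "</xs:sequence></xs:complexType></xs:element>"
        + scalar("Orf_Status")
        + scalar("Mechanism")
        + scalar("Product_Class")
        + '<xs:element name="Validation" minOccurs="0" maxOccurs="unbounded">'
        "<xs:complexType><xs:sequence>"
        + scalar("Outcome")
        + scalar("Note")
        + "</xs:sequence>"
        '<xs:attribute name="platform_ref" type="xs:string"/>'
        "</xs:complexType></xs:element>"
    )

    fusion_attrs = (
        '<xs:attribute name="sample_ref" type="nonEmptyString" use="required"/>'
        '<xs:attribute name="experiment_ref" type="xs:string"/>'
        '<xs:attribute name="mapping_algorithm_ref" type="xs:string"/>'
        '<xs:attribute name="fusion_detection_algorithm_ref" type="xs:string"/>'
        '<xs:attribute name="sequence_platform_ref" type="xs:string"/>'
    )

    lists = (
        list_el(
            "Source_List",
            item(
                "Source",
                scalar("Source_Type")
                + scalar("Pubmed_Id")
                + scalar("Title")
                + '<xs:element name="Author" type="xs:string" minOccurs="0" maxOccurs="unbounded"/>'
                + scalar("Year", "xs:integer")
                + scalar("Contact"),
            ),
        )
        + list_el(
            "Sample_List",
            item(
                "Sample",
                scalar("Organism", "nonEmptyString", required=True)
                + scalar("Tissue_Type", "nonEmptyString", required=True)
                + scalar("Disease")
                + scalar("Sample_Class")
                + scalar("Description"),
            ),
        )
        + list_el(
            "Experiment_List",
            item(
                "Experiment",
                scalar("Title") + scalar("Design_Description") + parameter,
            ),
        )
        + list_el(
            "Sequence_Platform_List",
            item(
                "Sequence_Platform",
                scalar("Name", "nonEmptyString", required=True)
                + scalar("Description")
                + scalar("Application_Type"),
            ),
        )
        + list_el(
            "Validation_Platform_List",
            item("Validation_Platform", scalar("Method") + scalar("Description")),
        )
        + list_el(
            "Mapping_Algorithm_List",
            item(
                "Mapping_Algorithm",
                scalar("Name", "nonEmptyString", required=True)
                + scalar("Version")
                + parameter,
            ),
        )
        + list_el(
            "Fusion_Detection_Algorithm_List",
            item(
                "Fusion_Detection_Algorithm",
                scalar("Name", "nonEmptyString", required=True)
                + scalar("Version")
                + parameter,
            ),
        )
        + list_el(
            "Sequence_Repository_List",
            item(
                "Sequence_Repository",
                scalar("Name") + scalar("Accession") + scalar("Uri"),
            ),
        )
        + list_el(
            "Gene_Fusion_List",
            item("Gene_Fusion", fusion_body, fusion_attrs),
        )
    )

    id_selector = "|".join(
        f"{list_name}/{item_name}" for _, list_name, item_name in _LIST_NAMES
    )
    keyrefs = "".join(
        f'<xs:keyref name="{name}Keyref" refer="recordElementIds">'
        f'<xs:selector xpath="{selector}"/><xs:field xpath="@{attr}"/></xs:keyref>'
        for name, selector, attr in (
            ("sample", "Gene_Fusion_List/Gene_Fusion", "sample_ref"),
            ("experiment", "Gene_Fusion_List/Gene_Fusion", "experiment_ref"),
            ("mapping", "Gene_Fusion_List/Gene_Fusion", "mapping_algorithm_ref"),
            (
                "fusionDetection",
                "Gene_Fusion_List/Gene_Fusion",
                "fusion_detection_algorithm_ref",
            ),
            ("seqPlatform", "Gene_Fusion_List/Gene_Fusion", "sequence_platform_ref"),
            (
                "validationPlatform",
                "Gene_Fusion_List/Gene_Fusion/Validation",
                "platform_ref",
            ),
        )
    )

    schema = (
        '<?xml version="1.0" encoding="UTF-8"?>'
        '<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">'
        '<xs:simpleType name="nonEmptyString">'
        '<xs:restriction base="xs:string"><xs:minLength value="1"/></xs:restriction>'
        "</xs:simpleType>"
        '<xs:simpleType name="strandType">'
        '<xs:restriction base="xs:string">'
        '<xs:enumeration value="+"/><xs:enumeration value="-"/>'
        "</xs:restriction></xs:simpleType>"
        '<xs:simpleType name="dinucleotideType">'
        '<xs:restriction base="xs:string"><xs:pattern value="[ACGTacgt]{2}"/>'
        "</xs:restriction></xs:simpleType>"
        '<xs:simpleType name="readSequenceType">'
        '<xs:restriction base="xs:string"><xs:pattern value="[ACGTNacgtn]+"/>'
        "</xs:restriction></xs:simpleType>"
        '<xs:simpleType name="nonNegativeFloat">'
        '<xs:restriction base="xs:double"><xs:minInclusive value="0"/>'
        "</xs:restriction></xs:simpleType>"
        '<xs:element name="Record_Set">'
        "<xs:complexType><xs:sequence>"
        '<xs:element name="Record" maxOccurs="unbounded">'
        f"<xs:complexType><xs:sequence>{lists}</xs:sequence>"
        '<xs:attribute name="id" type="nonEmptyString" use="required"/>'
        "</xs:complexType>"
        '<xs:key name="recordElementIds">'
        f'<xs:selector xpath="{id_selector}"/><xs:field xpath="@id"/></xs:key>'
        f"{keyrefs}"
        "</xs:element>"
        "</xs:sequence>"
        '<xs:attribute name="format_version" type="xs:string"/>'
        "</xs:complexType>"
        '<xs:unique name="recordIds">'
        '<xs:selector xpath="Record"/><xs:field xpath="@id"/></xs:unique>'
        "</xs:element>"
        "</xs:schema>"
    )
    # round-trip through lxml for stable pretty-printed output
    parsed = etree.fromstring(schema.encode("utf-8"))
    return etree.tostring(
        parsed, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


def compiled_schema() -> etree.XMLSchema:
    """The exported schema compiled for document validation."""
    return etree.XMLSchema(etree.fromstring(export_schema().encode("utf-8")))


def schema_validates(document: str, schema: Optional[etree.XMLSchema] = None) -> bool:
    """Whether document text validates against the exported schema."""
    if schema is None:
        schema = compiled_schema()
    return schema.validate(_parse(document))


# ---------------------------------------------------------------------------
# tabular import

_PARTNER_FIELDS = ("gene_symbol", "chrom", "pos", "strand", "exon")
_EVIDENCE_FIELDS = ("junction_reads", "spanning_pairs", "rpkm", "unique_reads")


@dataclass
class ColumnMap:
    """Maps fusion-caller table columns onto GFML fusion fields.

    Gene symbols and breakpoint positions of both partners must be
    mapped; everything else is optional and defaults to unknown/absent.
    """

    gene_symbol_5p: str
    gene_symbol_3p: str
    pos_5p: str
    pos_3p: str
    chrom_5p: Optional[str] = None
    chrom_3p: Optional[str] = None
    strand_5p: Optional[str] = None
    strand_3p: Optional[str] = None
    exon_5p: Optional[str] = None
    exon_3p: Optional[str] = None
    fusion_id: Optional[str] = None
    junction_reads: Optional[str] = None
    spanning_pairs: Optional[str] = None
    rpkm: Optional[str] = None
    unique_reads: Optional[str] = None

    @classmethod
    def from_dict(cls, mapping: dict) -> "ColumnMap":
        known = {f.name for f in dataclass_fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise GfmlError(
                f"unknown column-map fields: {sorted(unknown)}; "
                f"known fields: {sorted(known)}"
            )
        missing = {"gene_symbol_5p", "gene_symbol_3p", "pos_5p", "pos_3p"} - set(mapping)
        if missing:
            raise GfmlError(
                f"column map must map partner gene symbols and breakpoints; "
                f"missing: {sorted(missing)}"
            )
        return cls(**mapping)

    @classmethod
    def from_file(cls, path: str) -> "ColumnMap":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise GfmlError(f"column map file {path!r} must be a mapping")
        return cls.from_dict(data)

    def mapped_columns(self) -> list[str]:
        return [
            getattr(self, f.name)
            for f in dataclass_fields(self)
            if getattr(self, f.name) is not None
        ]


@dataclass(frozen=True)
class RowError:
    row: int  # 1-based data-row number (header excluded)
    message: str


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def import_fusion_table(
    rows: str,
    column_map: ColumnMap,
    source: model.SourceInfo,
    sample: model.SampleInfo,
    mapping_algorithm: Optional[model.MappingAlgorithm] = None,
    fusion_detection_algorithm: Optional[model.FusionDetectionAlgorithm] = None,
    sequence_platform: Optional[model.SequencePlatform] = None,
    record_id: str = "R_import",
    on_error: str = "raise",
) -> tuple[Record, list[RowError]]:
    """Build a record from generic fusion-caller tabular output.

    ``rows`` is delimited text (tab or comma, auto-detected from the
    required header row).  Each data row becomes one fusion referencing
    the supplied sample/source provenance.  ``on_error`` is ``raise`` or
    ``skip``; with ``skip`` unparsable rows are reported in the returned
    list and the remaining rows imported.

    The imported record passes validation by construction (mechanism is
    inferred from partner geometry; unmapped optional fields stay
    unknown).
    """
    from .fusion_semantics import infer_mechanism

    if on_error not in ("raise", "skip"):
        raise GfmlError(f"on_error must be 'raise' or 'skip', not {on_error!r}")
    lines = rows.splitlines()
    if not lines:
        raise GfmlError("empty table: a header row is required")
    delimiter = _detect_delimiter(lines[0])
    parsed = list(csv.DictReader(io.StringIO(rows), delimiter=delimiter))
    header = lines[0].split(delimiter)
    missing = [c for c in column_map.mapped_columns() if c not in header]
    if missing:
        raise GfmlError(
            f"mapped column(s) {missing} not found in header {header}"
        )

    def get(row: dict, column: Optional[str]) -> Optional[str]:
        if column is None:
            return None
        value = (row.get(column) or "").strip()
        return value or None

    fusions: list[model.GeneFusion] = []
    errors: list[RowError] = []
    for i, row in enumerate(parsed, 1):
        try:
            partners = []
            for side in ("5p", "3p"):
                pos_raw = get(row, getattr(column_map, f"pos_{side}"))
                if pos_raw is None:
                    raise GfmlError(f"missing breakpoint position (pos_{side})")
                try:
                    pos = int(pos_raw.replace(",", ""))
                except ValueError:
                    raise GfmlError(
                        f"unparsable coordinate {pos_raw!r} in pos_{side}"
                    ) from None
                exon_raw = get(row, getattr(column_map, f"exon_{side}"))
                partners.append(
                    model.FusionPartner(
                        role="five_prime" if side == "5p" else "three_prime",
                        gene_symbol=get(row, getattr(column_map, f"gene_symbol_{side}"))
                        or "",
                        chromosome=get(row, getattr(column_map, f"chrom_{side}"))
                        or "unknown",
                        strand=get(row, getattr(column_map, f"strand_{side}")) or "+",
                        breakpoint=pos,
                        exon_number=int(exon_raw) if exon_raw else None,
                    )
                )
            five_prime, three_prime = partners
            evidence = None
            if any(
                getattr(column_map, f) is not None for f in _EVIDENCE_FIELDS
            ):
                jr = get(row, column_map.junction_reads)
                sp = get(row, column_map.spanning_pairs)
                rp = get(row, column_map.rpkm)
                ur = get(row, column_map.unique_reads)
                evidence = model.ReadEvidence(
                    junction_read_count=int(jr) if jr else 0,
                    spanning_pair_count=int(sp) if sp else 0,
                    rpkm=float(rp) if rp else None,
                    unique_read_count=int(ur) if ur else None,
                )
            fusion = model.GeneFusion(
                id=get(row, column_map.fusion_id) or f"F{i}",
                five_prime=five_prime,
                three_prime=three_prime,
                sample_ref=sample.id,
                evidence=evidence,
                mechanism=infer_mechanism(five_prime, three_prime),
                mapping_algorithm_ref=mapping_algorithm.id if mapping_algorithm else None,
                fusion_detection_algorithm_ref=(
                    fusion_detection_algorithm.id if fusion_detection_algorithm else None
                ),
                sequence_platform_ref=sequence_platform.id if sequence_platform else None,
            )
            fusions.append(fusion)
        except (GfmlError, ValueError) as exc:
            if on_error == "raise":
                raise GfmlError(f"row {i}: {exc}") from exc
            errors.append(RowError(row=i, message=str(exc)))
    if not fusions:
        raise GfmlError("no importable rows; gene_fusion is a mandatory category")
    record = model.new_record(
        record_id,
        sources=[source],
        samples=[sample],
        gene_fusions=fusions,
        mapping_algorithms=[mapping_algorithm] if mapping_algorithm else None,
        fusion_detection_algorithms=(
            [fusion_detection_algorithm] if fusion_detection_algorithm else None
        ),
        sequence_platforms=[sequence_platform] if sequence_platform else None,
    )
    return record, errors


# ---------------------------------------------------------------------------
# BEDPE export

def export_bedpe(record_set: RecordSet) -> str:
    """One BEDPE line per fusion, 1-based closed breakpoints converted to
    0-based half-open single-base intervals (start = breakpoint - 1)."""
    lines = []
    for record in record_set.records:
        for f in record.gene_fusions:
            name = f"{f.five_prime.gene_symbol}--{f.three_prime.gene_symbol}"
            score = f.evidence.junction_read_count if f.evidence else 0
            lines.append(
                "\t".join(
                    str(x)
                    for x in (
                        f.five_prime.chromosome,
                        f.five_prime.breakpoint - 1,
                        f.five_prime.breakpoint,
                        f.three_prime.chromosome,
                        f.three_prime.breakpoint - 1,
                        f.three_prime.breakpoint,
                        name,
                        score,
                        f.five_prime.strand,
                        f.three_prime.strand,
                    )
                )
            )
    return "\n".join(lines) + ("\n" if lines else "")
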