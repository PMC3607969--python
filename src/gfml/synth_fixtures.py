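"""Seeded synthetic record sets for testing every layer without downloads.

The generator emulates the *structure* of fusion-discovery studies — a
few records, each with provenance, specimen, platform and algorithm
metadata plus a list of fusion entries with junction, frame, mechanism
and read evidence — not the biology: gene symbols are drawn from a
bundled list of recurrent fusion partners irrespective of their true
chromosomes, and read sequences are uniform-random nucleotide strings.
Partner geometry is, however, kept consistent with the stored mechanism
(an inversion really does have opposite strands), junction dinucleotides
agree with the stored splice pattern, and the product class follows the
frame status, so semantic queries behave as they would on real data.

:func:`corrupt` injects exactly one kind of defect into a serialised
document, for exercising the validator and the exported schema.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Optional

from lxml import etree

from . import model
from .fusion_semantics import classify_fusion_product, infer_mechanism
from .gfml_io import write_gfml
from .model import GfmlError, Record, RecordSet

__all__ = [
    "GeneratorConfig",
    "INJECTABLE_DEFECTS",
    "generate_record_set",
    "exemplar_tmprss2_erg",
    "corrupt",
]

# Recurrent fusion partners and other plausible cancer genes; symbols only,
# not tied to their true genomic locations.
GENE_SYMBOLS = (
    "TMPRSS2", "ERG", "ETV1", "ETV4", "ETV5", "SLC45A3", "ALK", "EML4",
    "BRAF", "RAF1", "KIAA1549", "BCR", "ABL1", "PML", "RARA", "RUNX1",
    "RUNX1T1", "ETV6", "NTRK1", "NTRK2", "NTRK3", "RET", "KIF5B", "CCDC6",
    "ROS1", "CD74", "FGFR2", "FGFR3", "TACC3", "EWSR1", "FLI1", "WT1",
    "SS18", "SSX1", "PAX3", "FOXO1", "MYB", "NFIB", "FUS", "DDIT3",
    "TFE3", "PRCC", "MET", "EGFR", "NOTCH1", "MAST1", "MAST2", "AKT3",
    "CIC", "DUX4",
)

# Toy genome: chromosome label -> length in bases (megabase-scale,
# loosely modelled on the human assembly).
CHROMOSOME_SIZES: dict[str, int] = {
    "chr1": 248_000_000, "chr2": 242_000_000, "chr3": 198_000_000,
    "chr4": 190_000_000, "chr5": 181_000_000, "chr6": 170_000_000,
    "chr7": 159_000_000, "chr8": 145_000_000, "chr9": 138_000_000,
    "chr10": 133_000_000, "chr11": 135_000_000, "chr12": 133_000_000,
    "chr13": 114_000_000, "chr14": 107_000_000, "chr15": 101_000_000,
    "chr16": 90_000_000, "chr17": 83_000_000, "chr18": 80_000_000,
    "chr19": 58_000_000, "chr20": 64_000_000, "chr21": 46_000_000,
    "chr22": 50_000_000, "chrX": 156_000_000, "chrY": 57_000_000,
}

TISSUES = ("prostate", "lung", "breast", "colon", "liver", "blood", "brain")
DISEASES = (
    "prostate carcinoma", "lung adenocarcinoma", "breast carcinoma",
    "colorectal carcinoma", "hepatocellular carcinoma",
    "chronic myeloid leukemia", "glioblastoma", "leiomyosarcoma",
)
SEQ_PLATFORMS = (
    "Illumina HiSeq 2000", "Illumina Genome Analyzer II", "ABI SOLiD 4",
    "Roche 454 GS FLX",
)
VALIDATION_METHODS = ("FISH", "qRT-PCR", "RT-PCR", "Sanger", "aCGH")
MAPPING_ALGORITHMS = ("Bowtie", "BWA", "TopHat", "MAQ")
FUSION_ALGORITHMS = ("ShortFuse", "deFuse", "ChimeraScan", "FusionSeq", "TopHat-Fusion")
DOMAIN_NAMES = (
    "protein kinase", "SH2", "SH3", "ETS DNA-binding", "zinc finger",
    "helix-loop-helix", "coiled coil", "transmembrane",
)

INJECTABLE_DEFECTS = (
    "MISSING_MANDATORY",
    "EMPTY_LIST",
    "DUPLICATE_ID",
    "DANGLING_REF",
    "VOCAB_VIOLATION",
    "COORD_INVALID",
    "STRAND_INVALID",
    "PATTERN_MISMATCH",
)


@dataclass
class GeneratorConfig:
    """Recipe for a synthetic record set.

    The class fractions reflect what fusion-discovery candidate lists
    look like: a minority of candidates are in frame, most carry read
    evidence (retaining it is the format's point), and only a fraction
    have been orthogonally validated.
    """

    seed: int = 0
    n_records: int = 3
    fusions_per_record: int = 5
    fraction_in_frame: float = 0.3
    fraction_validated: float = 0.25
    fraction_with_reads: float = 0.8
    fraction_canonical_junction: float = 0.8
    mechanism_weights: dict[str, float] = field(
        default_factory=lambda: {
            "translocation": 0.35,
            "deletion": 0.2,
            "read_through": 0.1,
            "inversion": 0.15,
            "tandem_duplication": 0.1,
            "trans_splicing": 0.05,
        }
    )
    read_length: int = 50
    populate_all_categories: bool = True

    def __post_init__(self) -> None:
        if self.n_records < 1 or self.fusions_per_record < 1:
            raise GfmlError("n_records and fusions_per_record must be >= 1")
        for name in (
            "fraction_in_frame",
            "fraction_validated",
            "fraction_with_reads",
            "fraction_canonical_junction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise GfmlError(f"{name} must be in [0, 1], got {value}")
        if any(w < 0 for w in self.mechanism_weights.values()):
            raise GfmlError("mechanism weights must be nonnegative")
        if not any(self.mechanism_weights.values()):
            raise GfmlError("mechanism weights must not all be zero")
        unknown = set(self.mechanism_weights) - set(model.MECHANISMS)
        if unknown:
            raise GfmlError(f"unknown mechanisms in weights: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str) -> "GeneratorConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise GfmlError(f"generator config {path!r} must be a mapping")
        return cls(**data)


def _random_sequence(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def _draw_mechanism(rng: random.Random, weights: dict[str, float]) -> str:
    names = sorted(weights)
    return rng.choices(names, weights=[weights[n] for n in names], k=1)[0]


def _partner_geometry(rng: random.Random, mechanism: str):
    """Chromosomes, strands and breakpoints consistent with ``mechanism``."""
    chroms = sorted(CHROMOSOME_SIZES)
    strand = rng.choice("+-")

    def pos(chrom: str, lo: int = 1, hi: Optional[int] = None) -> int:
        return rng.randint(lo, hi or CHROMOSOME_SIZES[chrom])

    if mechanism in ("translocation", "trans_splicing"):
        c5, c3 = rng.sample(chroms, 2)
        return (c5, strand, pos(c5)), (c3, rng.choice("+-"), pos(c3))
    chrom = rng.choice(chroms)
    size = CHROMOSOME_SIZES[chrom]
    if mechanism == "inversion":
        other = "+" if strand == "-" else "-"
        return (chrom, strand, pos(chrom)), (chrom, other, pos(chrom))
    if mechanism in ("deletion", "read_through"):
        if mechanism == "read_through":
            gap = rng.randint(5_000, 900_000)
        else:
            gap = rng.randint(1_500_000, size // 2)
        upstream = rng.randint(1, size - gap - 1)
        b5, b3 = (upstream, upstream + gap) if strand == "+" else (upstream + gap, upstream)
        return (chrom, strand, b5), (chrom, strand, b3)
    # tandem duplication: 5' breakpoint strictly downstream of the 3' one
    gap = rng.randint(1_000, size // 2)
    upstream = rng.randint(1, size - gap - 1)
    b3, b5 = (upstream, upstream + gap) if strand == "+" else (upstream + gap, upstream)
    return (chrom, strand, b5), (chrom, strand, b3)


def _make_partner(
    rng: random.Random, role: str, symbol: str, geometry, validated_boundary: bool
) -> model.FusionPartner:
    chrom, strand, breakpoint = geometry
    boundary = rng.choices(
        ("exon_boundary", "within_exon", "intronic", "intergenic"),
        weights=(0.6, 0.2, 0.1, 0.1),
        k=1,
    )[0]
    domains = []
    if rng.random() < 0.5:
        for name in rng.sample(DOMAIN_NAMES, rng.randint(1, 2)):
            domains.append(
                model.DomainAnnotation(
                    name=name,
                    accession=f"PF{rng.randint(1, 99999):05d}",
                    status=rng.choices(
                        model.DOMAIN_STATUSES, weights=(0.6, 0.2, 0.2), k=1
                    )[0],
                )
            )
    return model.FusionPartner(
        role=role,
        gene_symbol=symbol,
        chromosome=chrom,
        strand=strand,
        breakpoint=breakpoint,
        exon_number=rng.randint(1, 20),
        boundary_class=boundary,
        domains=domains,
    )


def _make_fusion(
    rng: random.Random,
    config: GeneratorConfig,
    fusion_id: str,
    record: Record,
) -> model.GeneFusion:
    symbol_5p, symbol_3p = rng.sample(GENE_SYMBOLS, 2)
    mechanism = _draw_mechanism(rng, config.mechanism_weights)
    geom_5p, geom_3p = _partner_geometry(rng, mechanism)
    five_prime = _make_partner(rng, "five_prime", symbol_5p, geom_5p, False)
    three_prime = _make_partner(rng, "three_prime", symbol_3p, geom_3p, False)

    if rng.random() < config.fraction_in_frame:
        orf_status = "in_frame"
    else:
        orf_status = rng.choices(
            ("out_of_frame", "promoter_swap", "non_coding"),
            weights=(0.7, 0.15, 0.15),
            k=1,
        )[0]

    if rng.random() < config.fraction_canonical_junction:
        donor, acceptor, pattern = "GT", "AG", "canonical"
    else:
        donor, acceptor = rng.choice((("GC", "AG"), ("AT", "AC"), ("CT", "AC")))
        pattern = "non_canonical"
    junction = model.SpliceJunction(
        donor_dinucleotide=donor,
        acceptor_dinucleotide=acceptor,
        pattern=pattern,
        junction_sequence=_random_sequence(rng, 20),
    )

    evidence = None
    if rng.random() < config.fraction_with_reads:
        n_reads = rng.randint(1, 3)
        evidence = model.ReadEvidence(
            junction_read_count=rng.randint(1, 120),
            spanning_pair_count=rng.randint(0, 60),
            rpkm=round(rng.expovariate(1 / 30.0), 2),
            unique_read_count=rng.randint(1, 80),
            reads=[
                (f"{fusion_id}_read{k}", _random_sequence(rng, config.read_length))
                for k in range(1, n_reads + 1)
            ],
        )

    validations = []
    if record.validation_platforms and rng.random() < config.fraction_validated:
        platform = rng.choice(record.validation_platforms)
        validations.append(
            model.ValidationResult(
                platform_ref=platform.id,
                outcome=rng.choices(
                    ("validated", "not_validated"), weights=(0.8, 0.2), k=1
                )[0],
            )
        )

    return model.GeneFusion(
        id=fusion_id,
        five_prime=five_prime,
        three_prime=three_prime,
        sample_ref=rng.choice(record.samples).id,
        junction=junction,
        evidence=evidence,
        orf_status=orf_status,
        mechanism=mechanism,
        product_class=classify_fusion_product(orf_status),
        validations=validations,
        experiment_ref=rng.choice(record.experiments).id if record.experiments else None,
        mapping_algorithm_ref=(
            rng.choice(record.mapping_algorithms).id if record.mapping_algorithms else None
        ),
        fusion_detection_algorithm_ref=(
            rng.choice(record.fusion_detection_algorithms).id
            if record.fusion_detection_algorithms
            else None
        ),
        sequence_platform_ref=(
            rng.choice(record.sequence_platforms).id if record.sequence_platforms else None
        ),
    )


def _make_record(rng: random.Random, config: GeneratorConfig, index: int) -> Record:
    rid = f"R{index}"
    sources = [
        model.SourceInfo(
            id="SRC1",
            source_type="publication",
            pubmed_id=str(rng.randint(10_000_000, 29_999_999)),
            title=f"Transcriptome study {index}",
            authors=[f"Author_{rng.randint(1, 500)}", f"Author_{rng.randint(501, 999)}"],
            year=rng.randint(2008, 2012),
        )
    ]
    tissue = rng.choice(TISSUES)
    samples = [
        model.SampleInfo(
            id=f"SAM{k}",
            organism="Homo sapiens",
            tissue_type=tissue,
            disease=rng.choice(DISEASES),
            sample_class=rng.choices(
                model.SAMPLE_CLASSES, weights=(0.6, 0.3, 0.05, 0.05), k=1
            )[0],
        )
        for k in range(1, rng.randint(1, 2) + 1)
    ]
    record = Record(id=rid, sources=sources, samples=samples)
    if config.populate_all_categories:
        record.experiments = [
            model.ExperimentInfo(
                id="EXP1",
                title="Paired-end transcriptome sequencing",
                parameters=[("library_type", "paired-end"), ("read_length", "50")],
            )
        ]
        record.sequence_platforms = [
            model.SequencePlatform(
                id=f"SQP{k}", name=name, application_type="transcriptome"
            )
            for k, name in enumerate(rng.sample(SEQ_PLATFORMS, rng.randint(1, 2)), 1)
        ]
        record.validation_platforms = [
            model.ValidationPlatform(id=f"VAP{k}", method=method)
            for k, method in enumerate(
                rng.sample(VALIDATION_METHODS, rng.randint(1, 2)), 1
            )
        ]
        record.mapping_algorithms = [
            model.MappingAlgorithm(
                id="MAP1",
                name=rng.choice(MAPPING_ALGORITHMS),
                version=f"0.{rng.randint(1, 12)}",
                parameters=[("max_mismatches", str(rng.randint(0, 3)))],
            )
        ]
        record.fusion_detection_algorithms = [
            model.FusionDetectionAlgorithm(
                id="FDA1",
                name=rng.choice(FUSION_ALGORITHMS),
                version=f"1.{rng.randint(0, 9)}",
            )
        ]
        record.sequence_repositories = [
            model.SequenceRepository(
                id="REP1",
                name="Sequence Read Archive",
                accession=f"SRX{rng.randint(100000, 999999)}",
                uri=None,
            )
        ]
    record.gene_fusions = [
        _make_fusion(rng, config, f"F{k}", record)
        for k in range(1, config.fusions_per_record + 1)
    ]
    return model.new_record(
        record.id,
        sources=record.sources,
        samples=record.samples,
        gene_fusions=record.gene_fusions,
        experiments=record.experiments or None,
        sequence_platforms=record.sequence_platforms or None,
        validation_platforms=record.validation_platforms or None,
        mapping_algorithms=record.mapping_algorithms or None,
        fusion_detection_algorithms=record.fusion_detection_algorithms or None,
        sequence_repositories=record.sequence_repositories or None,
    )


def generate_record_set(config: Optional[GeneratorConfig] = None, **overrides) -> RecordSet:
    """Generate a record set from a seeded recipe.

    The same configuration always yields an identical set (and identical
    serialised bytes).  The output passes strict validation and validates
    against the exported schema.  Keyword overrides are applied on top of
    ``config`` (or the defaults), e.g. ``generate_record_set(seed=42)``.
    """
    if config is None:
        config = GeneratorConfig()
    if overrides:
        config = replace(config, **overrides)
    rng = random.Random(config.seed)
    records = [_make_record(rng, config, i) for i in range(1, config.n_records + 1)]
    return RecordSet(records=records)


def exemplar_tmprss2_erg() -> Record:
    """The proof-of-concept record: the recurrent prostate-cancer
    TMPRSS2–ERG fusion, with synthetic placeholder coordinates and reads.

    TMPRSS2 contributes its untranslated first exon, placing ERG under
    androgen-responsive control — a promoter swap arising by interstitial
    deletion on chromosome 21.  Coordinates, read sequences and counts
    here are illustrative placeholders, not measurements.
    """
    source = model.SourceInfo(
        id="SRC1",
        source_type="publication",
        pubmed_id="19167416",
        title="Transcriptome sequencing re-discovers the TMPRSS2-ERG fusion",
        authors=["Maher CA"],
        year=2009,
    )
    sample = model.SampleInfo(
        id="SAM1",
        organism="Homo sapiens",
        tissue_type="prostate",
        disease="prostate carcinoma",
        sample_class="tissue",
    )
    platform = model.SequencePlatform(
        id="SQP1", name="Illumina Genome Analyzer II", application_type="transcriptome"
    )
    validation_platform = model.ValidationPlatform(id="VAP1", method="FISH")
    mapping = model.MappingAlgorithm(id="MAP1", name="Bowtie", version="0.12")
    detection = model.FusionDetectionAlgorithm(id="FDA1", name="ShortFuse", version="1.0")
    five_prime = model.FusionPartner(
        role="five_prime",
        gene_symbol="TMPRSS2",
        chromosome="chr21",
        strand="-",
        breakpoint=42_880_008,
        exon_number=1,
        boundary_class="exon_boundary",
    )
    three_prime = model.FusionPartner(
        role="three_prime",
        gene_symbol="ERG",
        chromosome="chr21",
        strand="-",
        breakpoint=39_817_544,
        exon_number=4,
        boundary_class="exon_boundary",
        domains=[
            model.DomainAnnotation(
                name="ETS DNA-binding", accession="PF00178", status="retained"
            )
        ],
    )
    fusion = model.GeneFusion(
        id="F1",
        five_prime=five_prime,
        three_prime=three_prime,
        sample_ref="SAM1",
        junction=model.SpliceJunction(
            donor_dinucleotide="GT",
            acceptor_dinucleotide="AG",
            pattern="canonical",
            junction_sequence="CAGGAGGCGGAGGCGGAGGGCGAGGGGCGG",
        ),
        evidence=model.ReadEvidence(
            junction_read_count=42,
            spanning_pair_count=17,
            rpkm=74.5,
            unique_read_count=38,
            reads=[
                ("read1", "ACAGGAGGCGGAGGCGGAGGGCGAGGGGCGGGGAGCGCCGCCTGGAGCGC"),
                ("read2", "TAGGCGCGAGCTAAGCAGGAGGCGGAGGCGGAGGGCGAGGGGCGGGGAGC"),
            ],
        ),
        orf_status="promoter_swap",
        mechanism="deletion",
        product_class="promoter_swap",
        validations=[
            model.ValidationResult(platform_ref="VAP1", outcome="validated")
        ],
        experiment_ref=None,
        mapping_algorithm_ref="MAP1",
        fusion_detection_algorithm_ref="FDA1",
        sequence_platform_ref="SQP1",
    )
    assert infer_mechanism(five_prime, three_prime) == "deletion"
    return model.new_record(
        "R_TMPRSS2_ERG",
        sources=[source],
        samples=[sample],
        gene_fusions=[fusion],
        sequence_platforms=[platform],
        validation_platforms=[validation_platform],
        mapping_algorithms=[mapping],
        fusion_detection_algorithms=[detection],
    )


# ---------------------------------------------------------------------------
# defect injection

def corrupt(record_set: RecordSet, defect: str, seed: int = 0) -> str:
    """Serialise ``record_set`` and inject exactly one defect kind.

    Returns document text guaranteed to elicit at least the requested
    finding code from lenient validation (and, for structural codes, to
    fail the exported schema).  Deterministic for a given seed.

    Raises
    ------
    GfmlError
        If ``defect`` is unknown, or the set offers no injection site
        (e.g. no splice junction for PATTERN_MISMATCH).
    """
    if defect not in INJECTABLE_DEFECTS:
        raise GfmlError(
            f"uninjectable defect {defect!r}; choose from {INJECTABLE_DEFECTS}"
        )
    rng = random.Random(seed)
    root = etree.fromstring(write_gfml(record_set).encode("utf-8"))

    def pick(xpath: str, what: str) -> etree._Element:
        nodes = root.findall(xpath)
        if not nodes:
            raise GfmlError(f"cannot inject {defect}: no {what} in the record set")
        return rng.choice(nodes)

    if defect == "MISSING_MANDATORY":
        target = pick("Record/Sample_List", "Sample_List")
        target.getparent().remove(target)
    elif defect == "EMPTY_LIST":
        lists = [el for el in root.findall("Record/*") if el.tag.endswith("_List")]
        target = rng.choice(lists)
        for child in list(target):
            target.remove(child)
    elif defect == "DUPLICATE_ID":
        record = pick("Record", "Record")
        with_id = [el for el in record.findall("*/*") if el.get("id")]
        if len(with_id) < 2:
            raise GfmlError("cannot inject DUPLICATE_ID: fewer than two elements")
        a, b = rng.sample(with_id, 2)
        b.set("id", a.get("id"))
    elif defect == "DANGLING_REF":
        fusion = pick("Record/Gene_Fusion_List/Gene_Fusion", "Gene_Fusion")
        fusion.set("sample_ref", "MISSING_TARGET")
    elif defect == "VOCAB_VIOLATION":
        target = pick("Record/Gene_Fusion_List/Gene_Fusion/Mechanism", "Mechanism")
        target.text = "inverson"
    elif defect == "COORD_INVALID":
        target = pick(
            "Record/Gene_Fusion_List/Gene_Fusion/*/Breakpoint", "Breakpoint"
        )
        target.text = "0"
    elif defect == "STRAND_INVALID":
        target = pick("Record/Gene_Fusion_List/Gene_Fusion/*/Strand", "Strand")
        target.text = "."
    else:  # PATTERN_MISMATCH
        junction = pick(
            "Record/Gene_Fusion_List/Gene_Fusion/Splice_Junction", "Splice_Junction"
        )
        for name, text in (
            ("Donor_Dinucleotide", "GT"),
            ("Acceptor_Dinucleotide", "AG"),
            ("Pattern", "non_canonical"),
        ):
            child = junction.find(name)
            if child is None:
                child = etree.SubElement(junction, name)
            child.text = text
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")
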