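"""Derived fusion attributes: splice pattern, reading frame, product class,
breakpoint boundary class and rearrangement mechanism.

The reading-frame rule works on two quantities the exon junction fixes:
the number of coding bases the 5' partner retains (start codon to
breakpoint, inclusive) and the native codon phase of the first retained
coding base of the 3' partner.  The fusion is in frame exactly when
``coding_len_5p mod 3`` equals that phase, i.e. when the ribosome arrives
at the junction in the same sub-codon position the 3' exon expects.
A 5' partner contributing no coding sequence onto a coding 3' segment is
a promoter swap; a non-coding 3' segment makes the product non-coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import FusionPartner, GfmlError

__all__ = [
    "FrameInput",
    "ExonModel",
    "classify_splice_pattern",
    "compute_orf_status",
    "classify_fusion_product",
    "classify_boundary",
    "infer_mechanism",
    "READ_THROUGH_MAX_GAP",
]

#: Same-chromosome, same-strand deletion-like events with a breakpoint gap
#: below this many bases are classified as transcriptional read-through
#: rather than genomic deletion.  1 Mb is generous for adjacent-gene
#: read-through; tune per annotation density.
READ_THROUGH_MAX_GAP = 1_000_000

_VALID_DINUCLEOTIDE = frozenset(
    a + b for a in "ACGT" for b in "ACGT"
)

#: Minor-spliceosome and other recognised non-GT–AG pairs, reported in the
#: informational note when seen.
_MINOR_PAIRS = {"GC-AG", "AT-AC"}


def classify_splice_pattern(donor: str, acceptor: str) -> str:
    """Classify an intron's boundary dinucleotides.

    ``canonical`` iff donor is GT and acceptor is AG; every other pair,
    including the minor-spliceosome GC–AG and AT–AC pairs, is
    ``non_canonical``.

    Raises
    ------
    GfmlError
        If either argument is not two bases of ACGT (case-insensitive).
    """
    donor = (donor or "").upper()
    acceptor = (acceptor or "").upper()
    for label, dinucleotide in (("donor", donor), ("acceptor", acceptor)):
        if dinucleotide not in _VALID_DINUCLEOTIDE:
            raise GfmlError(
                f"{label} dinucleotide {dinucleotide!r} must be two of ACGT"
            )
    return "canonical" if (donor, acceptor) == ("GT", "AG") else "non_canonical"


def splice_pattern_note(donor: str, acceptor: str) -> Optional[str]:
    """Informational note for recognised minor-spliceosome pairs."""
    pair = f"{(donor or '').upper()}-{(acceptor or '').upper()}"
    if pair in _MINOR_PAIRS:
        return f"{pair} is a recognised minor-spliceosome pair"
    return None


@dataclass
class FrameInput:
    """Inputs the frame rule needs, all derivable from exon-level junction
    coordinates and the partners' CDS annotations.

    coding_len_5p
        Coding bases retained in the 5' partner, start codon to breakpoint
        inclusive.  ``None`` when the 5' CDS annotation is unknown; 0 when
        the breakpoint precedes the start codon (UTR-only contribution).
    phase_3p
        Native codon phase (0, 1 or 2) of the first retained coding base
        of the 3' partner; ``None`` when unknown.
    three_prime_coding
        Whether the retained 3' segment overlaps its gene's coding region.
    """

    coding_len_5p: Optional[int] = None
    phase_3p: Optional[int] = None
    three_prime_coding: bool = True

    def __post_init__(self) -> None:
        if self.coding_len_5p is not None and self.coding_len_5p < 0:
            raise GfmlError("coding_len_5p must be >= 0")
        if self.phase_3p is not None and self.phase_3p not in (0, 1, 2):
            raise GfmlError("phase_3p must be 0, 1 or 2")


def compute_orf_status(f: FrameInput) -> str:
    """Infer the reading-frame status of the fusion product.

    Returns one of ``in_frame``, ``out_of_frame``, ``promoter_swap``,
    ``non_coding`` or ``unknown`` (the sink for missing information).
    """
    if not f.three_prime_coding:
        return "non_coding"
    if f.coding_len_5p is None or f.coding_len_5p == 0:
        # 5' partner contributes only untranslated/regulatory sequence
        return "promoter_swap" if f.coding_len_5p == 0 else "unknown"
    if f.phase_3p is None:
        return "unknown"
    return "in_frame" if f.coding_len_5p % 3 == f.phase_3p else "out_of_frame"


def classify_fusion_product(orf_status: str, has_retained_5p_domain: bool = False) -> str:
    """Map reading-frame status to the class of the fusion product.

    An in-frame junction yields a chimeric fusion protein; out-of-frame
    truncates the 5' protein at the junction; promoter swaps and
    non-coding fusions map to their own classes.  ``has_retained_5p_domain``
    is carried for annotation (a truncated product with no retained domain
    is rarely of interest) but does not change the class.
    """
    return {
        "in_frame": "fusion_protein",
        "out_of_frame": "truncated_protein",
        "promoter_swap": "promoter_swap",
        "non_coding": "non_coding",
    }.get(orf_status, "unknown")


@dataclass
class ExonModel:
    """Ordered exon intervals of one gene, 1-based closed coordinates.

    ``gene_span`` defaults to the hull of the exons; give it explicitly to
    include regulatory flanks.
    """

    exons: list[tuple[int, int]] = field(default_factory=list)
    strand: str = "+"
    gene_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        exons = sorted(tuple(e) for e in self.exons)
        for start, end in exons:
            if start > end:
                raise GfmlError(f"exon ({start}, {end}) has start > end")
        for (_, prev_end), (next_start, _) in zip(exons, exons[1:]):
            if next_start <= prev_end:
                raise GfmlError("exons overlap")
        self.exons = exons
        if self.gene_span is None and exons:
            self.gene_span = (exons[0][0], exons[-1][1])

    @classmethod
    def from_bed(cls, path: str, strand: str = "+") -> "ExonModel":
        """Load exons from a BED-like file (chrom, start, end[, strand]);
        on-disk 0-based half-open intervals become 1-based closed here."""
        exons = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise GfmlError(f"BED line needs >=3 columns: {line!r}")
                exons.append((int(parts[1]) + 1, int(parts[2])))
                if len(parts) >= 4 and parts[3] in ("+", "-"):
                    strand = parts[3]
        return cls(exons=exons, strand=strand)


def classify_boundary(breakpoint: int, exons: ExonModel) -> str:
    """Place a breakpoint relative to a gene's exon structure.

    ``exon_boundary`` when it coincides with an exon start or end,
    ``within_exon`` strictly inside an exon, ``intronic`` inside the gene
    span but in no exon, ``intergenic`` outside the span, and ``unknown``
    for an empty exon model.
    """
    if not exons.exons:
        return "unknown"
    for start, end in exons.exons:
        if breakpoint == start or breakpoint == end:
            return "exon_boundary"
        if start < breakpoint < end:
            return "within_exon"
    span_start, span_end = exons.gene_span
    if span_start <= breakpoint <= span_end:
        return "intronic"
    return "intergenic"


def infer_mechanism(
    p5: FusionPartner,
    p3: FusionPartner,
    read_through_max_gap: int = READ_THROUGH_MAX_GAP,
) -> str:
    """Infer the genomic rearrangement class from partner geometry.

    Different chromosomes imply a translocation; same chromosome with
    opposite strands an inversion.  On the same chromosome and strand the
    5' breakpoint lying upstream of the 3' breakpoint (in transcription
    direction) is deletion-like — called ``read_through`` when the gap is
    below ``read_through_max_gap``, ``deletion`` otherwise — and the 5'
    breakpoint lying downstream is a tandem duplication.  Missing fields
    give ``unknown``.
    """
    for partner in (p5, p3):
        if (
            partner is None
            or not partner.chromosome
            or partner.strand not in ("+", "-")
            or partner.breakpoint is None
        ):
            return "unknown"
    if p5.chromosome != p3.chromosome:
        return "translocation"
    if p5.strand != p3.strand:
        return "inversion"
    # transcription runs left-to-right on '+', right-to-left on '-'
    if p5.strand == "+":
        five_prime_upstream = p5.breakpoint <= p3.breakpoint
    else:
        five_prime_upstream = p5.breakpoint >= p3.breakpoint
    if five_prime_upstream:
        gap = abs(p3.breakpoint - p5.breakpoint)
        return "read_through" if gap < read_through_max_gap else "deletion"
    return "tandem_duplication"
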