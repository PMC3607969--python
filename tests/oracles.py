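"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written from first principles — flat
dictionaries and linear scans — and never calls the code paths it
checks.
"""

from __future__ import annotations

import random


# ---------------------------------------------------------------------------
# brute-force query evaluation over flattened fusions

def flatten_fusion(fusion, record) -> dict[str, list]:
    """Materialise every queryable value of one fusion as a flat dict.

    Raises KeyError if a populated reference does not resolve (the caller
    treats that fusion as excluded).
    """
    by_id = {}
    for attr in (
        "sources", "samples", "experiments", "sequence_platforms",
        "validation_platforms", "mapping_algorithms",
        "fusion_detection_algorithms", "sequence_repositories", "gene_fusions",
    ):
        for el in getattr(record, attr):
            by_id[el.id] = el

    def deref(ref):
        if not ref:
            return None
        return by_id[ref]  # KeyError on dangling

    p5, p3 = fusion.five_prime, fusion.three_prime
    sample = deref(fusion.sample_ref)
    values: dict[str, list] = {
        "gene_symbol": [p5.gene_symbol, p3.gene_symbol],
        "five_prime.gene_symbol": [p5.gene_symbol],
        "three_prime.gene_symbol": [p3.gene_symbol],
        "sample.tissue_type": [sample.tissue_type] if sample and sample.tissue_type else [],
        "sample.disease": [sample.disease] if sample and sample.disease else [],
        "sample.organism": [sample.organism] if sample and sample.organism else [],
        "sample.sample_class": [sample.sample_class] if sample and sample.sample_class else [],
        "source.pubmed_id": [s.pubmed_id for s in record.sources if s.pubmed_id],
        "source.author": [a for s in record.sources for a in s.authors],
        "domain.name": [d.name for p in (p5, p3) for d in p.domains],
        "domain.status": [d.status for p in (p5, p3) for d in p.domains],
        "domain.partner_role": [p.role for p in (p5, p3) for _ in p.domains],
        "domain.broken_name": [
            d.name for p in (p5, p3) for d in p.domains if d.status in ("broken", "lost")
        ],
        "five_prime.domain.name": [d.name for d in p5.domains],
        "three_prime.domain.name": [d.name for d in p3.domains],
        "orf_status": [fusion.orf_status],
        "product_class": [fusion.product_class],
        "mechanism": [fusion.mechanism],
        "junction.pattern": [fusion.junction.pattern] if fusion.junction else [],
        "partner.boundary_class": [p5.boundary_class, p3.boundary_class],
        "five_prime.boundary_class": [p5.boundary_class],
        "three_prime.boundary_class": [p3.boundary_class],
        "validation.outcome": [v.outcome for v in fusion.validations],
    }
    methods = []
    for v in fusion.validations:
        platform = deref(v.platform_ref)
        if platform is not None and platform.method:
            methods.append(platform.method)
    values["validation.platform.method"] = methods
    for key, ref in (
        ("platform.name", fusion.sequence_platform_ref),
        ("mapping_algorithm.name", fusion.mapping_algorithm_ref),
        ("fusion_detection_algorithm.name", fusion.fusion_detection_algorithm_ref),
    ):
        el = deref(ref)
        name = getattr(el, "name", None) if el is not None else None
        values[key] = [name] if name else []
    ev = fusion.evidence
    values["evidence.present"] = [True] if ev is not None else []
    values["evidence.reads"] = [len(ev.reads)] if ev is not None else []
    values["evidence.rpkm"] = [ev.rpkm] if ev is not None and ev.rpkm is not None else []
    values["evidence.unique_read_count"] = (
        [ev.unique_read_count] if ev is not None and ev.unique_read_count is not None else []
    )
    values["evidence.junction_read_count"] = [ev.junction_read_count] if ev else []
    return values


def _number(x):
    if isinstance(x, bool):
        return None
    try:
        return float(x)
    except (TypeError, ValueError):
        return None


def eval_predicate_dict(node: dict, values: dict[str, list]) -> bool:
    """Interpret the JSON form of a predicate against flattened values."""
    if "all_of" in node:
        return all(eval_predicate_dict(c, values) for c in node["all_of"])
    if "any_of" in node:
        return any(eval_predicate_dict(c, values) for c in node["any_of"])
    if "not" in node:
        return not eval_predicate_dict(node["not"], values)
    field, op, target = node["field"], node["op"], node.get("value")
    vs = [v for v in values[field] if v is not None]
    if op == "exists":
        want = True if target is None else str(target).strip().lower() in ("true", "1", "yes")
        return bool(vs) == want
    for v in vs:
        if op == "equals":
            a, b = _number(v), _number(target)
            if a is not None and b is not None:
                if a == b:
                    return True
            elif str(v).lower() == str(target).lower():
                return True
        elif op == "contains":
            if str(target).lower() in str(v).lower():
                return True
        elif op in ("ge", "le"):
            a, b = _number(v), _number(target)
            if a is not None and b is not None and ((a >= b) if op == "ge" else (a <= b)):
                return True
        elif op == "in_set":
            members = target if isinstance(target, (list, tuple, set)) else [
                m for m in str(target).strip("[]{}").replace(",", " ").split()
            ]
            if str(v).lower() in {str(m).lower() for m in members}:
                return True
    return False


def scan_query(record_set, predicate) -> tuple[list[tuple[str, str]], int]:
    """Unoptimised linear scan; returns (matches, n_excluded_for_dangling)."""
    node = predicate.to_dict()
    matches, excluded = [], 0
    for record in record_set.records:
        for fusion in record.gene_fusions:
            try:
                values = flatten_fusion(fusion, record)
            except KeyError:
                excluded += 1
                continue
            if eval_predicate_dict(node, values):
                matches.append((record.id, fusion.id))
    return matches, excluded


# ---------------------------------------------------------------------------
# translation oracle for the reading-frame rule

_STOPLESS_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def random_junction(rng: random.Random):
    """A toy 5' CDS prefix and 3' CDS cut mid-gene; returns
    (retained_5p, cds3, cut_index) with retained 5' length >= 1."""
    cds5 = "ATG" + "".join(rng.choice(_STOPLESS_CODONS) for _ in range(rng.randint(4, 20)))
    cds3 = "ATG" + "".join(rng.choice(_STOPLESS_CODONS) for _ in range(rng.randint(12, 30)))
    retained_len = rng.randint(1, len(cds5))
    cut = rng.randint(3, len(cds3) - 30)  # keep >= 10 distal codons
    return cds5[:retained_len], cds3, cut


def frame_status_by_translation(retained_5p: str, cds3: str, cut: int) -> str:
    """Call in/out of frame by translating the fused CDS and asking
    whether the distal native peptide of the 3' gene is preserved."""
    from Bio.Seq import Seq

    fused = retained_5p + cds3[cut:]
    first_full = cut + (-cut) % 3  # first native codon start at/after the cut
    n_codons = (len(cds3) - first_full) // 3
    native_tail = str(Seq(cds3[first_full : first_full + 3 * n_codons]).translate())
    fused_trimmed = fused[: len(fused) - len(fused) % 3]
    fused_pep = str(Seq(fused_trimmed).translate())
    return "in_frame" if native_tail and fused_pep.endswith(native_tail) else "out_of_frame"


# ---------------------------------------------------------------------------
# boundary classification by naive interval scan

def boundary_by_scan(breakpoint: int, exons: list[tuple[int, int]], span) -> str:
    if not exons:
        return "unknown"
    for start, end in exons:
        if breakpoint in (start, end):
            return "exon_boundary"
    for start, end in exons:
        if start < breakpoint < end:
            return "within_exon"
    if span[0] <= breakpoint <= span[1]:
        return "intronic"
    return "intergenic"


# ---------------------------------------------------------------------------
# plain Levenshtein for suggestion cross-checks

def levenshtein(a: str, b: str) -> int:
    rows = [list(range(len(b) + 1))]
    for i, ca in enumerate(a, 1):
        row = [i]
        for j, cb in enumerate(b, 1):
            row.append(
                min(rows[i - 1][j] + 1, row[j - 1] + 1, rows[i - 1][j - 1] + (ca != cb))
            )
        rows.append(row)
    return rows[-1][-1]
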