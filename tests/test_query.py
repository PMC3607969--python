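"""Query compilation, evaluation semantics and the 17-query catalogue."""

import random

import pytest

from gfml.model import RecordSet
from gfml.query import (
    AllOf,
    AnyOf,
    Atom,
    Not,
    QueryError,
    SELECTORS,
    compile_query,
    run_query,
    table1_suite,
)
from gfml.synth_fixtures import generate_record_set

from conftest import minimal_record
from oracles import scan_query


class TestCompile:
    def test_simple_atom(self):
        predicate = compile_query("gene_symbol equals ERG")
        assert predicate == Atom("gene_symbol", "equals", "ERG")

    def test_not_over_exists(self):
        predicate = compile_query("not evidence.present exists")
        assert isinstance(predicate, Not)
        assert predicate.child.operator == "exists"

    def test_parenthesized_boolean_combination(self):
        predicate = compile_query(
            '(sample.tissue_type equals prostate or sample.tissue_type equals lung) '
            "and orf_status equals in_frame"
        )
        assert isinstance(predicate, AllOf)
        assert isinstance(predicate.children[0], AnyOf)

    def test_quoted_values_keep_spaces(self):
        predicate = compile_query('sample.disease contains "prostate carcinoma"')
        assert predicate.value == "prostate carcinoma"

    def test_unknown_selector_suggests_nearest(self):
        with pytest.raises(QueryError, match="gene_symbol"):
            compile_query("genesymbol equals ERG")

    def test_unknown_operator_lists_valid_ones(self):
        with pytest.raises(QueryError, match="contains"):
            compile_query("gene_symbol matches ERG")

    def test_json_structured_form_is_equivalent(self):
        text_form = compile_query("gene_symbol equals ERG and evidence.rpkm ge 50")
        json_form = compile_query(
            '{"all_of": [{"field": "gene_symbol", "op": "equals", "value": "ERG"},'
            ' {"field": "evidence.rpkm", "op": "ge", "value": 50}]}'
        )
        assert text_form.to_dict() == json_form.to_dict()


class TestRunQuery:
    def test_either_partner_matches_gene_symbol(self, exemplar_set):
        for symbol in ("ERG", "TMPRSS2", "erg"):
            assert run_query(exemplar_set, Atom("gene_symbol", "equals", symbol)).count == 1
        assert run_query(exemplar_set, Atom("gene_symbol", "equals", "ALK")).count == 0

    def test_empty_result_has_count_zero(self, small_set):
        result = run_query(small_set, Atom("sample.tissue_type", "equals", "nonesuch"))
        assert result.matches == [] and result.count == 0

    def test_dangling_reference_excludes_fusion_with_warning(self):
        record = minimal_record()
        record.gene_fusions[0].sequence_platform_ref = "NOPE"
        record_set = RecordSet(records=[record])
        result = run_query(record_set, Atom("platform.name", "contains", "Illumina"))
        assert result.count == 0
        assert len(result.warnings) == 1

    def test_absent_optional_field_matches_only_exists_false(self):
        record = minimal_record()  # fusion has no evidence
        record_set = RecordSet(records=[record])
        assert run_query(record_set, Atom("evidence.rpkm", "ge", 0)).count == 0
        assert run_query(record_set, Atom("evidence.present", "exists", False)).count == 1

    def test_result_order_is_record_then_fusion_order(self, small_set):
        result = run_query(small_set, Not(Atom("gene_symbol", "equals", "")))
        expected = [
            (r.id, f.id) for r in small_set.records for f in r.gene_fusions
        ]
        assert result.matches == expected


def _random_predicate(rng: random.Random, depth: int = 0):
    atoms = [
        ("gene_symbol", "equals", rng.choice(["ERG", "ALK", "BCR", "TMPRSS2"])),
        ("sample.tissue_type", "equals", rng.choice(["prostate", "lung", "blood"])),
        ("sample.disease", "contains", rng.choice(["carcinoma", "leukemia"])),
        ("orf_status", "equals", rng.choice(["in_frame", "out_of_frame"])),
        ("mechanism", "in_set", ("inversion", "deletion")),
        ("junction.pattern", "equals", "non_canonical"),
        ("evidence.rpkm", rng.choice(["ge", "le"]), rng.choice([5, 30, 80])),
        ("evidence.present", "exists", rng.choice([True, False])),
        ("validation.platform.method", "equals", rng.choice(["FISH", "Sanger"])),
        ("five_prime.boundary_class", "equals", "intergenic"),
        ("domain.name", "contains", rng.choice(["kinase", "SH"])),
        ("platform.name", "contains", "Illumina"),
    ]
    if depth >= 2 or rng.random() < 0.4:
        return Atom(*rng.choice(atoms))
    kind = rng.randrange(3)
    if kind == 0:
        return Not(_random_predicate(rng, depth + 1))
    children = tuple(_random_predicate(rng, depth + 1) for _ in range(rng.randint(2, 3)))
    return AllOf(children) if kind == 1 else AnyOf(children)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(1, 11))
    def test_random_predicates_equal_brute_force_scan(self, seed):
        record_set = generate_record_set(seed=seed, n_records=3, fusions_per_record=8)
        rng = random.Random(seed * 1000)
        for _ in range(20):
            predicate = _random_predicate(rng)
            expected, _ = scan_query(record_set, predicate)
            assert run_query(record_set, predicate).matches == expected

    def test_de_morgan_consistency(self, small_set):
        a = Atom("orf_status", "equals", "in_frame")
        b = Atom("evidence.present", "exists", True)
        left = run_query(small_set, Not(AnyOf((a, b)))).matches
        right = run_query(small_set, AllOf((Not(a), Not(b)))).matches
        assert left == right

    def test_rpkm_threshold_monotonicity(self, small_set):
        previous = None
        for threshold in (0, 10, 30, 60, 120, 10**6):
            matches = set(run_query(small_set, Atom("evidence.rpkm", "ge", threshold)).matches)
            if previous is not None:
                assert matches <= previous
            previous = matches


class TestTable1Suite:
    def test_suite_has_seventeen_entries(self):
        suite = table1_suite()
        assert len(suite) == 17

    def test_all_suite_selectors_are_registered(self):
        def atoms(node):
            if isinstance(node, Atom):
                yield node
            elif isinstance(node, Not):
                yield from atoms(node.child)
            else:
                for child in node.children:
                    yield from atoms(child)

        for predicate in table1_suite().values():
            for atom in atoms(predicate):
                assert atom.field_path in SELECTORS

    def test_validation_platform_entry_matches_only_resolved_fish(self):
        record_set = generate_record_set(
            seed=5, n_records=4, fusions_per_record=10, fraction_validated=0.8
        )
        predicate = table1_suite(validation_method="FISH")["validation_platform"]
        result = run_query(record_set, predicate)
        fusions = {
            (r.id, f.id): (f, r) for r in record_set.records for f in r.gene_fusions
        }
        for key, (fusion, record) in fusions.items():
            methods = set()
            for v in fusion.validations:
                platform = next(
                    p for p in record.validation_platforms if p.id == v.platform_ref
                )
                methods.add(platform.method)
            assert (key in set(result.matches)) == ("FISH" in methods)

    def test_splice_boundary_entry_is_five_prime_intergenic_only(self, small_set):
        result = run_query(small_set, table1_suite()["splice_boundary"])
        fusions = {
            (r.id, f.id): f for r in small_set.records for f in r.gene_fusions
        }
        for key, fusion in fusions.items():
            expected = fusion.five_prime.boundary_class == "intergenic"
            assert ((key in set(result.matches)) == expected)

    def test_suite_entries_match_brute_force_scan(self, small_set):
        for name, predicate in table1_suite().items():
            expected, _ = scan_query(small_set, predicate)
            assert run_query(small_set, predicate).matches == expected, name

    def test_exemplar_queries(self, exemplar_set):
        suite = table1_suite(gene="ERG", tissue="prostate")
        assert run_query(exemplar_set, suite["gene_identifier"]).count == 1
        assert run_query(exemplar_set, suite["sample_type"]).count == 1
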