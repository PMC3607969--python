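"""Validator findings, mandatory/optional rules and vocabulary checks."""

import copy
import random

import pytest

from gfml import model
from gfml.model import CATEGORY_LABELS, MANDATORY_CATEGORIES, RecordSet, drop_category
from gfml.validation import (
    DEFAULT_REGISTRY,
    VocabularyError,
    VocabularyRegistry,
    check_vocabulary,
    validate,
)

from conftest import minimal_record
from oracles import levenshtein


class TestMandatoryRule:
    def test_record_without_samples_fails_with_missing_mandatory(self):
        record = minimal_record()
        record.samples.clear()
        report = validate(RecordSet(records=[record]))
        assert not report.is_valid
        assert "MISSING_MANDATORY" in report.error_codes()

    def test_valid_generated_set_has_no_findings(self, small_set):
        report = validate(small_set, strict=True)
        assert report.is_valid
        assert report.findings == []

    def test_dangling_sample_ref_is_reported(self):
        record = minimal_record()
        record.gene_fusions[0].sample_ref = "SX"
        report = validate(RecordSet(records=[record]))
        assert "DANGLING_REF" in report.error_codes()
        # oracle: exhaustive scan confirms SX is nowhere in the record
        assert all(el.id != "SX" for _, el in record.elements())

    @pytest.mark.parametrize("label", CATEGORY_LABELS)
    def test_deleting_one_category_fails_iff_mandatory(self, full_record, label):
        dropped = drop_category(full_record, label)
        report = validate(RecordSet(records=[dropped]))
        if label in MANDATORY_CATEGORIES:
            assert not report.is_valid
            missing = [
                f
                for f in report.findings
                if f.code == "MISSING_MANDATORY" and f.severity == "error"
                and f.path.endswith(label)
            ]
            assert len(missing) == 1
        else:
            assert report.is_valid


class TestReportProperties:
    def test_validate_is_idempotent_and_order_insensitive(self, small_set):
        record = minimal_record()
        record.gene_fusions[0].sample_ref = "SX"
        record.samples[0].tissue_type = ""
        base = RecordSet(records=[record, copy.deepcopy(small_set.records[0])])
        shuffled = RecordSet(records=list(reversed(copy.deepcopy(base.records))))
        codes = lambda rep: sorted(f.code for f in rep.findings)
        first = validate(base)
        assert codes(first) == codes(validate(base))  # idempotent
        assert codes(first) == codes(validate(shuffled))  # order-insensitive

    def test_findings_are_sorted_by_path_then_code(self):
        record = minimal_record()
        record.gene_fusions[0].sample_ref = "SX"
        record.gene_fusions[0].five_prime.breakpoint = 0
        report = validate(RecordSet(records=[record]))
        keys = [(f.path, f.code, f.message) for f in report.findings]
        assert keys == sorted(keys)

    def test_strict_mode_promotes_vocabulary_findings_to_errors(self):
        record = minimal_record()
        record.gene_fusions[0].mechanism = "inverson"
        record_set = RecordSet(records=[record])
        assert validate(record_set).is_valid  # warning only
        strict = validate(record_set, strict=True)
        assert not strict.is_valid
        assert "VOCAB_VIOLATION" in strict.error_codes()

    def test_pattern_contradicting_dinucleotides_is_flagged(self):
        record = minimal_record()
        record.gene_fusions[0].junction = model.SpliceJunction(
            donor_dinucleotide="GT", acceptor_dinucleotide="AG", pattern="non_canonical"
        )
        report = validate(RecordSet(records=[record]))
        assert "PATTERN_MISMATCH" in report.error_codes()


class TestVocabulary:
    def test_case_insensitive_hit_returns_canonical_casing(self):
        result = check_vocabulary("fish", "validation_methods")
        assert result.ok and result.canonical == "FISH"

    def test_empty_term_is_a_violation(self):
        assert not check_vocabulary("", "mechanisms").ok

    def test_near_miss_gets_nearest_term_suggestion(self):
        result = check_vocabulary("inverson", "mechanisms")
        assert not result.ok
        assert result.suggestion == "inversion"

    def test_unknown_vocabulary_name_lists_known_ones(self):
        with pytest.raises(VocabularyError, match="mechanisms"):
            check_vocabulary("x", "no_such_vocabulary")

    def test_suggestion_matches_min_edit_distance_with_alpha_tiebreak(self):
        """Cross-check suggestions against an independent Levenshtein."""
        rng = random.Random(0)
        for name in DEFAULT_REGISTRY.names():
            terms = DEFAULT_REGISTRY.terms(name)
            for _ in range(5):
                term = rng.choice(terms)
                i = rng.randrange(len(term))
                mutated = term[:i] + rng.choice("xyz") + term[i + 1 :]
                result = DEFAULT_REGISTRY.check(mutated, name)
                if result.ok:
                    continue  # mutation hit another term case-insensitively
                best = min(
                    sorted(terms),
                    key=lambda t: levenshtein(mutated.lower(), t.lower()),
                )
                assert result.suggestion == best

    def test_registry_loadable_from_yaml_file(self, tmp_path):
        path = tmp_path / "vocab.yaml"
        path.write_text("validation_methods: [ddPCR]\nmy_terms: [alpha, beta]\n")
        registry = VocabularyRegistry.from_file(str(path))
        assert registry.check("ddpcr", "validation_methods").ok
        assert registry.check("FISH", "validation_methods").ok  # base kept
        assert registry.check("beta", "my_terms").ok
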