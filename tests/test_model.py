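"""Record construction rules, reference resolution and category counts."""

import pytest
from hypothesis import given, settings, strategies as st

from gfml import model
from gfml.model import (
    CATEGORY_LABELS,
    ConstructionError,
    RecordSet,
    new_record,
    record_stats,
    resolve_reference,
)
from gfml.synth_fixtures import generate_record_set

from conftest import minimal_record


class TestNewRecord:
    def test_minimal_record_is_constructible(self):
        record = minimal_record()
        assert record.populated_categories() == ["source", "sample", "gene_fusion"]

    @pytest.mark.parametrize("missing", ["source", "sample", "gene_fusion"])
    def test_empty_mandatory_list_is_rejected_by_name(self, missing):
        template = minimal_record()
        kwargs = {
            "sources": template.sources,
            "samples": template.samples,
            "gene_fusions": template.gene_fusions,
        }
        kwargs[
            {"source": "sources", "sample": "samples", "gene_fusion": "gene_fusions"}[missing]
        ] = []
        with pytest.raises(ConstructionError) as excinfo:
            new_record("R1", **kwargs)
        assert excinfo.value.code == "MISSING_MANDATORY"
        assert missing in str(excinfo.value)

    def test_duplicate_id_across_categories_is_rejected(self):
        template = minimal_record()
        template.samples[0].id = "SRC1"  # collides with the source id
        with pytest.raises(ConstructionError) as excinfo:
            new_record(
                "R1",
                sources=template.sources,
                samples=template.samples,
                gene_fusions=template.gene_fusions,
            )
        assert excinfo.value.code == "DUPLICATE_ID"
        assert "SRC1" in str(excinfo.value)

    def test_fully_populated_record_exposes_nine_categories(self, full_record):
        assert len(full_record.populated_categories()) == 9
        assert set(full_record.populated_categories()) == set(CATEGORY_LABELS)

    @settings(derandomize=True, max_examples=200)
    @given(
        n_sources=st.integers(0, 2),
        n_samples=st.integers(0, 2),
        n_fusions=st.integers(0, 2),
        ids=st.lists(st.sampled_from(["A", "B", "C", "D", "E", "F"]), min_size=6, max_size=6),
    )
    def test_rejects_exactly_empty_mandatory_or_duplicate_id(
        self, n_sources, n_samples, n_fusions, ids
    ):
        """new_record rejects an input iff a mandatory list is empty or an
        id repeats — and accepts everything else."""
        it = iter(ids)
        sources = [model.SourceInfo(id=next(it), pubmed_id="1") for _ in range(n_sources)]
        samples = [
            model.SampleInfo(id=next(it), tissue_type="lung") for _ in range(n_samples)
        ]
        partner = lambda role: model.FusionPartner(
            role=role, gene_symbol="ALK", chromosome="chr2", strand="+", breakpoint=100
        )
        fusions = [
            model.GeneFusion(
                id=next(it),
                five_prime=partner("five_prime"),
                three_prime=partner("three_prime"),
                sample_ref=samples[0].id if samples else "X",
            )
            for _ in range(n_fusions)
        ]
        used = [e.id for e in sources + samples + fusions]
        should_fail = (
            not sources or not samples or not fusions or len(used) != len(set(used))
        )
        if should_fail:
            with pytest.raises(ConstructionError):
                new_record("R1", sources=sources, samples=samples, gene_fusions=fusions)
        else:
            assert new_record(
                "R1", sources=sources, samples=samples, gene_fusions=fusions
            ).id == "R1"


class TestResolveReference:
    def test_sample_ref_resolves_to_the_sample(self):
        record = minimal_record()
        element = resolve_reference(record, "SAM1")
        assert isinstance(element, model.SampleInfo)
        assert element.tissue_type == "prostate"

    def test_absent_id_gives_none_not_an_exception(self):
        assert resolve_reference(minimal_record(), "NOPE") is None

    def test_every_reference_in_generated_records_resolves(self, small_set):
        """Exhaustive scan: each *_ref matches exactly one element id."""
        for record in small_set.records:
            all_ids = [el.id for _, el in record.elements()]
            for fusion in record.gene_fusions:
                for _, target in fusion.refs():
                    assert all_ids.count(target) == 1
                    assert resolve_reference(record, target).id == target


class TestRecordStats:
    def test_minimal_record_counts(self):
        stats = record_stats(RecordSet(records=[minimal_record()]))
        assert stats["records"] == 1
        assert stats["source"] == stats["sample"] == stats["gene_fusion"] == 1
        assert all(
            stats[label] == 0
            for label in CATEGORY_LABELS
            if label not in ("source", "sample", "gene_fusion")
        )

    def test_counts_sum_over_generated_records(self):
        record_set = generate_record_set(seed=7, n_records=3, fusions_per_record=5)
        stats = record_stats(record_set)
        assert stats["records"] == 3
        assert stats["gene_fusion"] == 15

    def test_category_label_list_has_length_nine(self):
        assert len(CATEGORY_LABELS) == 9
        stats = record_stats(RecordSet(records=[minimal_record()]))
        assert list(stats)[1:] == list(CATEGORY_LABELS)
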