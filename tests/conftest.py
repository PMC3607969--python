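import pytest

from gfml import model
from gfml.synth_fixtures import exemplar_tmprss2_erg, generate_record_set


@pytest.fixture(scope="session")
def small_set():
    return generate_record_set(seed=42, n_records=2, fusions_per_record=10)


@pytest.fixture(scope="session")
def full_record():
    """One record with all nine element categories populated."""
    record = generate_record_set(seed=1, n_records=1, fusions_per_record=5).records[0]
    assert len(record.populated_categories()) == 9
    return record


@pytest.fixture(scope="session")
def exemplar_set():
    return model.RecordSet(records=[exemplar_tmprss2_erg()])


def minimal_record(record_id="R1"):
    """Smallest valid record: one source, one sample, one fusion."""
    return model.new_record(
        record_id,
        sources=[model.SourceInfo(id="SRC1", pubmed_id="12345678")],
        samples=[model.SampleInfo(id="SAM1", tissue_type="prostate")],
        gene_fusions=[
            model.GeneFusion(
                id="F1",
                five_prime=model.FusionPartner(
                    role="five_prime", gene_symbol="TMPRSS2",
                    chromosome="chr21", strand="+", breakpoint=42_880_008,
                ),
                three_prime=model.FusionPartner(
                    role="three_prime", gene_symbol="ERG",
                    chromosome="chr21", strand="+", breakpoint=39_817_544,
                ),
                sample_ref="SAM1",
            )
        ],
    )
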