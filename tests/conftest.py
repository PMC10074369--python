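import hypothesis
import pytest

from multicause import (
    compute_x_matrix,
    fixture_mapping,
    resolve_records,
    table1_fixture,
)

hypothesis.settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=60
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def four_cat_mapping():
    return fixture_mapping()


@pytest.fixture(scope="session")
def ten_records(four_cat_mapping):
    """The ten-record worked example, resolved to categories A-D."""
    return resolve_records(table1_fixture(), four_cat_mapping)


@pytest.fixture(scope="session")
def ten_record_xmatrix(ten_records, four_cat_mapping):
    return compute_x_matrix(ten_records, four_cat_mapping.categories)
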