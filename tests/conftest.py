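import pytest

from geneburden.cohort_model_io import (
    build_reference_cohort,
    candidate_panel,
    known_panel,
)
from geneburden.qualifying_filter import FilterConfig, select_qualifying


@pytest.fixture(scope="session")
def reference_cohort():
    return build_reference_cohort(seed=1)


@pytest.fixture(scope="session")
def panel96():
    return candidate_panel()


@pytest.fixture(scope="session")
def known5():
    return known_panel()


@pytest.fixture(scope="session")
def qualifying(reference_cohort, panel96):
    return select_qualifying(reference_cohort, FilterConfig(), panel96)
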