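import hypothesis
import pytest

from vaeval.resources import (
    default_categories,
    default_cmea_table,
    default_code_map,
)

hypothesis.settings.register_profile(
    "vaeval", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("vaeval")


@pytest.fixture(scope="session")
def categories():
    return default_categories()


@pytest.fixture(scope="session")
def code_map():
    return default_code_map()


@pytest.fixture(scope="session")
def cmea():
    return default_cmea_table()


@pytest.fixture(scope="session")
def small_bundle():
    """A small generated cohort shared across tests (read-only)."""
    from vaeval.synthetic import default_cohort_spec, generate_cohort

    return generate_cohort(default_cohort_spec(seed=42))


@pytest.fixture(scope="session")
def small_kept(small_bundle):
    from vaeval.workflow import filter_agreed_valid

    kept, audit = filter_agreed_valid(
        small_bundle.records,
        small_bundle.assignments,
        small_bundle.cmea,
        small_bundle.code_map,
    )
    return kept, audit
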