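import pytest
from hypothesis import HealthCheck, settings

from pmcpolicy import (
    default_schema,
    default_taxonomy,
    evaluate_policies,
    fixture_codings,
    fixtures,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def fixture_set():
    return fixtures()


@pytest.fixture(scope="session")
def fixture_results(schema):
    """The 15 published worked-example policies, scored and ranked."""
    return evaluate_policies(fixture_codings(), schema)


@pytest.fixture
def fixture_sheet(tmp_path, schema):
    """The published worked-example rows written as a SUMMARY coding sheet."""
    from pmcpolicy import save_codings

    path = tmp_path / "table_rows.csv"
    save_codings(fixture_codings(), schema, path)
    return path
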