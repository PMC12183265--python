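import pytest

from cardiosig import synthetic_faers as sf


@pytest.fixture(scope="session")
def table2_fixture():
    """The deterministic published-cohort fixture: (reports, expected signal
    table).  Session-scoped; treat as read-only."""
    return sf.fixture_from_table2()


@pytest.fixture(scope="session")
def fixture_lexicon():
    return sf.fixture_lexicon()


@pytest.fixture()
def small_config():
    """A small, fast generator configuration for unit tests."""
    return sf.SimulationConfig(
        n_reports=2000,
        drug_catalog=sf.skewed_catalog("D", 8),
        event_catalog=sf.skewed_catalog("E", 5),
        seed=7,
    )
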