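import pytest

from tetradscreen import default_curves, fixture_cohort, preselected_cutoffs, run_analysis


@pytest.fixture(scope="session")
def curves():
    return default_curves()


@pytest.fixture(scope="session")
def cutoffs():
    return preselected_cutoffs()


@pytest.fixture(scope="session")
def fixture_records():
    return fixture_cohort()


@pytest.fixture(scope="session")
def fixture_report(fixture_records):
    """The full analysis report on the packaged fixture cohort, computed
    once per session."""
    return run_analysis(fixture_records)
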