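import pytest

from eprowatch.cohort_simulator import build_study_fixture, study_fixture_decisions
from eprowatch.epro_core import load_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def study_cohort():
    return build_study_fixture()


@pytest.fixture(scope="session")
def study_decisions(study_cohort):
    return study_fixture_decisions(study_cohort)
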