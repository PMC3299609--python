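from datetime import date

import pytest

from shouldercoi import (
    SyntheticCohortConfig,
    Window,
    cost_cohort,
    generate_cohort,
    load_paper_margins,
)


@pytest.fixture(scope="session")
def paper_margins():
    return load_paper_margins()


@pytest.fixture(scope="session")
def default_config():
    return SyntheticCohortConfig()


@pytest.fixture(scope="session")
def study_window(default_config):
    return default_config.window


@pytest.fixture(scope="session")
def synthetic_cohort(default_config):
    """One default 204-patient cohort, fixed seed."""
    return generate_cohort(default_config, seed=42)


@pytest.fixture(scope="session")
def synthetic_summaries(synthetic_cohort, study_window):
    return cost_cohort(synthetic_cohort, study_window)


@pytest.fixture
def window_2009():
    return Window(date(2009, 1, 1), date(2009, 6, 30))
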