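import pytest

from myoscreen import CohortConfig, build_reference_tables, generate_cohort, label_cohort


@pytest.fixture(scope="session")
def tables():
    return build_reference_tables()


@pytest.fixture(scope="session")
def default_cohort():
    """Default 1006-subject synthetic cohort, fixed seed."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def labeled_cohort(default_cohort, tables):
    return label_cohort(default_cohort, tables)
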