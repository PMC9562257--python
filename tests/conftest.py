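import pytest
from hypothesis import settings

from vocfit import default_generator_spec, generate_cohort
from vocfit.reference import PREVALENCE, rank_matched_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table_cohort():
    """255-subject cohort whose FIT values sit at the printed confusion ranks."""
    return rank_matched_cohort()


@pytest.fixture(scope="session")
def calibrated_spec():
    """Marker models calibrated to the published operating points (n=255)."""
    return default_generator_spec(n_subjects=255, seed=11, fixed_counts=True)


@pytest.fixture(scope="session")
def small_cohort(calibrated_spec):
    return generate_cohort(calibrated_spec, PREVALENCE)


@pytest.fixture(scope="session")
def big_cohort(calibrated_spec):
    """10^5 subjects for Monte-Carlo recovery checks; drawn once per session."""
    from dataclasses import replace

    spec = replace(calibrated_spec, n_subjects=100_000, seed=17)
    return generate_cohort(spec, PREVALENCE)
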