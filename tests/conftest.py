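import pytest

from gaitspeed.features import build_feature_table
from gaitspeed.synthetic import generate_cohort, generate_subject_profile, synthesize_trial


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects x 3 paces, 90 s trials: enough windows for LOSO fits."""
    return generate_cohort(4, seed=7, duration=90.0)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return build_feature_table(small_cohort)


@pytest.fixture(scope="session")
def medium_trial():
    """One medium-pace 60 s trial with its generating profile."""
    profile = generate_subject_profile(1, "S01")
    return profile, synthesize_trial(profile, "medium", duration=60.0, seed=3)


@pytest.fixture(scope="session")
def benchmark_table():
    """The reference synthetic benchmark: 20 subjects, 360 s trials, 5 s windows."""
    trials = generate_cohort(20, seed=42, duration=360.0)
    return build_feature_table(trials)
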