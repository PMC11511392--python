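import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import physioid as pid
from physioid import synth

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """A handful of profiles for per-record tests."""
    return pid.sample_cohort(6, master_seed=0)


@pytest.fixture(scope="session")
def clean_ecg(cohort):
    rec, gt = synth.generate_record(cohort[0], "ECG", noise=synth.CLEAN)
    return rec, gt


@pytest.fixture(scope="session")
def small_matrices():
    """A 6-subject, 2-record cohort (moderate noise) for classifier tests."""
    return pid.build_cohort_matrices(
        n_subjects=6, records_per_subject=2, master_seed=0,
        windows_per_subject=8,
    )


@pytest.fixture(scope="session")
def default_matrices():
    """The full default study cohort: 25 subjects x 10 records, 20 windows."""
    return pid.build_cohort_matrices(master_seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
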