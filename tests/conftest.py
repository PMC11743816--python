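import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_design():
    from facehouse.task import generate_task_design

    return generate_task_design(seed=0)


@pytest.fixture(scope="session")
def short_design():
    """A ~6 s miniature run for tests that need very short scans."""
    from facehouse.task import generate_task_design

    return generate_task_design(
        n_blocks=1, stimuli_per_sequence=1, fixation_s=0.0, rest_s=0.0, seed=0
    )


@pytest.fixture(scope="session")
def large_cohort():
    """Default-calibration cohort at n = 200,000 with no planted effects."""
    from facehouse.cohort import CohortConfig, generate_cohort

    table, _ = generate_cohort(CohortConfig(n_children=200_000, seed=0))
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
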