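import numpy as np
import pytest

from mindtask import CohortSpec, Montage, generate_cohort, trials_to_sessions


@pytest.fixture
def toy_montage() -> Montage:
    """One centre electrode with three neighbours, for hand-checkable filters."""
    return Montage(
        name="toy4",
        labels=["X", "A", "B", "C"],
        positions={"X": (0, 0), "A": (1, 0), "B": (-1, 0), "C": (0, 1)},
        neighbors={"X": ["A", "B", "C"]},
    )


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    # small but full-shape study: 3 subjects x 3 sessions, balanced classes
    return CohortSpec(
        trials_per_task_per_session=2,
        trial_duration_s=1.5,
        sampling_rate_hz=256.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort_raw(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_raw):
    trials, _ = small_cohort_raw
    return trials_to_sessions(trials)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
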