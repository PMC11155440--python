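import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

from durcat.design import SUBSECOND, SECOND, build_duration_set, build_trial_schedule
from durcat.observer import ObserverParams, simulate_session


@pytest.fixture(scope="session")
def subsecond_set():
    return build_duration_set(SUBSECOND)


@pytest.fixture(scope="session")
def second_set():
    return build_duration_set(SECOND)


@pytest.fixture(scope="session")
def subsecond_schedule(subsecond_set):
    return build_trial_schedule(subsecond_set, seed=11)


@pytest.fixture()
def typical_observer():
    return ObserverParams(id="obs001", group="control", pse=0.5, weber=0.13)


@pytest.fixture()
def typical_session(typical_observer, subsecond_schedule):
    return simulate_session(typical_observer, subsecond_schedule, seed=42)


@pytest.fixture(scope="session")
def study_tables():
    """One simulated study cohort (22 control vs 15 DD, both ranges)."""
    from durcat.observer import study_cohort, simulate_cohort

    return simulate_cohort(study_cohort(seed=5))
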