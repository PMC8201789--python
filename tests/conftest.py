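import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from critspeed import (
    ModelFamily,
    Params,
    TrialSet,
    fit_battery,
    predict_time,
    reference_group_trials,
)

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.filter_too_much, HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def group_trials() -> TrialSet:
    """Group-mean pseudo-participant of the reference cohort."""
    return reference_group_trials()

@pytest.fixture(scope="session")
def group_battery(group_trials):
    return fit_battery(group_trials)


def exact_trials(family, params: Params, speeds, pid="exact") -> TrialSet:
    """Noise-free trials generated directly from a model family."""
    speeds = np.asarray(speeds, float)
    return TrialSet(pid, speeds, np.asarray(predict_time(family, params, speeds)))


@pytest.fixture(scope="session")
def two_param_exact() -> TrialSet:
    return exact_trials(ModelFamily.TWO_PARAM, Params(cs=4.0, d_prime=200.0), [4.5, 5.0, 5.5, 6.0])
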