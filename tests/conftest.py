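import numpy as np
import pytest
from hypothesis import settings

from ecgsurv.discrete_survival import SurvivalLabel
from ecgsurv.synthetic_ecg import SimConfig, simulate_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_labels(times, events):
    return [SurvivalLabel(record_id=f"s{i}", time_months=float(t),
                          event=int(e))
            for i, (t, e) in enumerate(zip(times, events))]


def random_censored_labels(rng, n):
    """Random censored dataset with heavy ties across the 12 bins."""
    times = rng.integers(1, 13, n) - rng.random(n) * 0.5
    events = rng.integers(0, 2, n)
    return make_labels(times, events)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-subject simulated cohort shared by read-only tests."""
    return simulate_cohort(SimConfig(n_subjects=40, seed=123))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
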