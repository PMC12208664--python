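import numpy as np
import pytest

from m6adyn import cohort_steady_state, sample_rates
from m6adyn.perturbation import ko_comparison


@pytest.fixture(scope="session")
def baseline_cohort():
    """The standard seeded population: n=2000, gamma(1,1) rates, S=10."""
    return sample_rates(2000, shape=1.0, rate=1.0, S=10.0, seed=11)


@pytest.fixture(scope="session")
def baseline_states(baseline_cohort):
    return cohort_steady_state(baseline_cohort)


@pytest.fixture(scope="session")
def baseline_ko(baseline_cohort):
    """Knockout contrast (localization shift + half-life ratios), computed once."""
    return ko_comparison(baseline_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
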