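import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oncosurrogacy.simulate import TrialScenario, simulate_trial_suite
from oncosurrogacy.survival import km_fit

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def censored_curve():
    """Four subjects: events at 2, 5, 7 with one censoring at 4."""
    return km_fit(([2.0, 4.0, 5.0, 7.0], [1, 0, 1, 1]))


@pytest.fixture(scope="session")
def exponential_curve():
    """KM fit of 50,000 uncensored draws from an exponential with median 10 months."""
    lam = np.log(2) / 10.0
    rng = np.random.default_rng(12345)
    times = rng.exponential(1.0 / lam, 50_000)
    return km_fit((times, np.ones(times.size, dtype=int)))


@pytest.fixture(scope="session")
def simulated_suite():
    """Ten simulated trials spanning post-delay hazard ratios 0.5–1.1.

    Two of the trials have a second experimental arm, mirroring the mix of
    two- and three-arm designs; 300 subjects per arm keeps the estimates
    tight enough for recovery checks while staying fast.
    """
    template = TrialScenario(n_per_arm=300)
    grid = np.linspace(0.5, 1.1, 10)
    suites, table = simulate_trial_suite(
        10, grid, template=template, three_arm_trials=2, seed=7
    )
    return suites, table
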