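import numpy as np
import pytest

from glycotraj.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort_2000():
    """One default 4-class cohort at n=2000 (the config's own seed)."""
    return generate_cohort(SimulationConfig(n_patients=2000))


@pytest.fixture(scope="session")
def large_cohort_20000():
    """A large default cohort for share/prevalence checks."""
    return generate_cohort(SimulationConfig(n_patients=20000), seed=1)


@pytest.fixture(scope="session")
def two_class_cohort():
    """Well-specified 2-class mixture for parameter-recovery checks."""
    cfg = SimulationConfig(
        n_patients=500,
        class_proportions=(0.5, 0.5),
        class_curves=((180.0, -2.0, 0.0), (120.0, 3.0, -0.15)),
        random_intercept_sd=5.0,
        residual_sd=5.0,
        outcome_intercept=-2.0,
    )
    return cfg, generate_cohort(cfg, seed=3)


def random_series(rng, n=None):
    """A random valid glucose series (times strictly increasing, <=24 h)."""
    n = n or int(rng.integers(3, 9))
    times = np.sort(rng.choice(np.arange(0, 97) / 4.0, size=n, replace=False))
    values = rng.uniform(45.0, 400.0, size=n)
    return times, values
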