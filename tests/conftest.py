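import numpy as np
import pandas as pd
import pytest

from odontofa import SimulationConfig, generate


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort at the default study conditions."""
    return generate(SimulationConfig(seed=20240615))


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort for fast unit tests (structure intact)."""
    return SimulationConfig(n_males=60, n_females=60, n_traits=10, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate(small_config)


@pytest.fixture
def toy_measurements():
    """One individual, three traits, both sides, replicate 1."""
    rows = []
    for t, (left, right) in {
        "t01": (5.00, 5.20),
        "t02": (4.00, 4.00),
        "t03": (6.10, 6.05),
    }.items():
        rows.append(("A", "F", t, "L", 1, left))
        rows.append(("A", "F", t, "R", 1, right))
    return pd.DataFrame(
        rows, columns=["individual_id", "sex", "trait_id", "side", "replicate", "value_mm"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
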