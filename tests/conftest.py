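import numpy as np
import pandas as pd
import pytest

from beliefbandit import TaskConfig, simulate_sessions


@pytest.fixture(scope="session")
def bifp_data() -> pd.DataFrame:
    """5 sessions x 500 trials simulated from a representative BIfp agent."""
    return simulate_sessions("BIfp", dict(beta=3.0, phi=0.5, q=0.05),
                             TaskConfig(n_trials=500), 5, seed=11)


@pytest.fixture(scope="session")
def small_bifp_data() -> pd.DataFrame:
    """2 sessions x 200 trials; enough for fast likelihood checks."""
    return simulate_sessions("BIfp", dict(beta=3.0, phi=0.5, q=0.05),
                             TaskConfig(n_trials=200), 2, seed=23)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
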