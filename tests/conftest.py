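import warnings

import numpy as np
import pandas as pd
import pytest

from pondvarpart import SimulationConfig, simulate_metacommunity


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # basis-size reductions, smoothing-bound hits and zero-variance species
    # drops are routine on tiny test inputs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated taxon with all three effects active."""
    cfg = SimulationConfig(n_ponds=20, n_species=30, seed=42)
    return simulate_metacommunity(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_predictors():
    r = np.random.default_rng(7)
    n = 60
    return pd.DataFrame(
        {
            "x": r.uniform(0.0, 1.0, n),
            "z": r.uniform(0.0, 1.0, n),
            "u": r.uniform(0.0, 1.0, n),
            "cx": r.uniform(0.0, 100.0, n),
            "cy": r.uniform(0.0, 100.0, n),
        }
    )
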