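import warnings

import numpy as np
import pandas as pd
import pytest

from telogel.densitometry import TLDistribution
from telogel.simulate import PopulationSimConfig, simulate_population

# singular random-effect fits are an expected, documented outcome on small
# simulated datasets; keep the test output readable
warnings.filterwarnings(
    "ignore", message="singular fit", category=UserWarning
)


def make_dist(positions, weights, individual_id="x", window=(1.636, 40.0)):
    return TLDistribution(
        individual_id=individual_id,
        positions_kb=np.asarray(positions, dtype=float),
        weights=np.asarray(weights, dtype=float),
        window_kb=window,
    )


@pytest.fixture(scope="session")
def population() -> pd.DataFrame:
    """A mid-sized simulated cross-fostered cohort shared across tests."""
    return simulate_population(PopulationSimConfig(n_pairs=20, seed=5))


@pytest.fixture(scope="session")
def small_population() -> pd.DataFrame:
    return simulate_population(PopulationSimConfig(n_pairs=6, seed=11))
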