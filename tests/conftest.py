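import numpy as np
import pytest

from causalfc.synthetic import GroundTruthModel, make_ground_truth, simulate_subject
from causalfc.timeseries import ROITimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_noise_ts(rng):
    """10 mutually independent white-noise regions, T = 300."""
    return ROITimeSeries(rng.normal(size=(300, 10)), [f"N{i}" for i in range(10)])


@pytest.fixture
def small_model():
    """10-region sparse model with lag and contemporaneous edges."""
    return make_ground_truth(10, 0.05, contemp_fraction=0.3, seed=7)


@pytest.fixture
def two_region_lag_model():
    """A -> B with lag-1 coefficient 0.7, no other structure."""
    lag = np.zeros((2, 2))
    lag[0, 1] = 0.7
    return GroundTruthModel(
        2, lag, np.zeros((2, 2)), region_labels=("A", "B")
    )


@pytest.fixture
def lag_ts(two_region_lag_model):
    return simulate_subject(two_region_lag_model, None, 1000, seed=11)
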