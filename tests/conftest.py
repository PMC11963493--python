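"""Shared fixtures: one simulated experiment reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from drydown.sensor_processing import SensorSeries
from drydown.synthetic_data import ExperimentConfig, simulate_drydown


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic experiment (truth, observations)."""
    return simulate_drydown(ExperimentConfig(seed=3))


@pytest.fixture()
def make_series():
    """Factory for short sensor series on a regular 15-min grid."""

    def _make(values, tree_id="T1", variable="heat_velocity",
              unit="cm h-1", quality=None):
        values = np.asarray(values, dtype=float)
        ts = pd.date_range("2021-07-06", periods=values.size, freq="15min")
        return SensorSeries(tree_id=tree_id, variable=variable, unit=unit,
                            timestamps=ts, values=values, quality=quality)

    return _make
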