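import numpy as np
import pandas as pd
import pytest

from bioregion.gridio import Grid, ScalarField, VelocityField


@pytest.fixture
def small_grid():
    """5x6 all-ocean grid at 0.5-degree spacing."""
    return Grid(np.arange(6) * 0.5, 35.0 + np.arange(5) * 0.5)


@pytest.fixture
def masked_grid():
    lon = np.arange(6) * 0.5
    lat = 35.0 + np.arange(5) * 0.5
    mask = np.zeros((5, 6), dtype=bool)
    mask[0, :2] = True
    return Grid(lon, lat, mask)


@pytest.fixture
def monthly_times():
    return pd.date_range("2005-01", periods=36, freq="MS")


def make_field(grid, values, times=None, name="f", units="u"):
    return ScalarField(grid, values, times, name, units)


def make_velocity(grid, u, v, times=None, units="m/s"):
    return VelocityField(ScalarField(grid, u, times, "u", units),
                        ScalarField(grid, v, times, "v", units))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
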