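import numpy as np
import pandas as pd
import pytest

from nichedrift.gridio import GridSpec
from nichedrift.synthdata import gen_coastline, gen_velocity_jet


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(lon_min=0.0, lat_min=-1.0, cell_size=0.1, n_lon=40, n_lat=20)


@pytest.fixture(scope="session")
def lps_grid() -> GridSpec:
    """Benguela-like dispersal domain: 0.08-degree strip along a meridional coast."""
    return GridSpec(lon_min=10.0, lat_min=-30.0, cell_size=0.08, n_lon=14, n_lat=70)


@pytest.fixture(scope="session")
def coast(lps_grid):
    return gen_coastline(60, "meridional", lps_grid)


@pytest.fixture(scope="session")
def jet_series(lps_grid, coast):
    """Northward jet with an offshore-deflection front above coastal cell 45."""
    coastal, land = coast
    front_lat = coastal.centers()[45, 1] + lps_grid.cell_size / 2
    dates = pd.date_range("2008-01-01", periods=66, freq="D")
    return gen_velocity_jet(
        lps_grid, dates, jet_speed=0.15, jet_direction="north",
        front_lat=float(front_lat), offshore_deflection=0.15,
        counter_current_speed=0.0, noise_sd=0.0, seed=1, land=land,
    )
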