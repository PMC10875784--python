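import numpy as np
import pytest

from whalenav.environment import GridAxis, TimeGridField
from whalenav.simulator import ScenarioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_recipe():
    """Small open-sea recipe: flat 100 m depth, constant wind floor, no sources."""
    return {
        "extent": [-2.5, 2.5, 53.0, 57.5],
        "resolution_deg": 0.25,
        "depth": {"kind": "open", "base_depth_m": 100.0},
        "current": {"kind": "none"},
        "wind_floor_db": 55.0,
    }


@pytest.fixture
def quiet_config(quiet_recipe):
    """Reduced-scale scenario: 10 whales, ~290 km south-to-north leg."""
    return ScenarioConfig(
        n_whales=10,
        start_box=(-0.5, 0.5, 53.2, 53.8),
        target=(0.0, 55.9),
        arrival_radius_km=50.0,
        duration_h=48.0,
        dt_h=0.25,
        n_repeats=2,
        seed=7,
        environment=quiet_recipe,
    )


def grid_field(lon, lat, values, times=(0.0,), units=""):
    return TimeGridField(GridAxis(np.asarray(lon, float), "lon"),
                         GridAxis(np.asarray(lat, float), "lat"),
                         np.asarray(times, float),
                         np.asarray(values, float), units)


@pytest.fixture
def make_field():
    return grid_field


def radial_field(centre_lon, centre_lat, amplitude, decay_per_deg,
                 lon, lat, times=(0.0,)):
    """Radially symmetric scalar surface for gradient-direction oracles."""
    glon, glat = np.meshgrid(np.asarray(lon, float), np.asarray(lat, float))
    r2 = (glon - centre_lon) ** 2 + (glat - centre_lat) ** 2
    vals = amplitude * np.exp(-decay_per_deg * r2)
    return grid_field(lon, lat, np.broadcast_to(vals, (len(times),) + vals.shape),
                      times=times)


@pytest.fixture
def make_radial_field():
    return radial_field
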