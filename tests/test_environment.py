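import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from whalenav.environment import (
    DegenerateBearingError,
    DomainError,
    GridAxis,
    LandMask,
    Position,
    TimeGridField,
    bearing,
    constant_field,
    deepest_water_direction,
    displace,
    from_csv,
    from_netcdf,
    interpolate,
    noise_descent_direction,
    to_csv,
    to_netcdf,
)

EARTH_R = 6371.0


# -- independent oracles -----------------------------------------------------


def sphere_vec(lon, lat):
    lam, phi = np.radians(lon), np.radians(lat)
    return np.array([np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam),
                     np.sin(phi)])


def oracle_distance_km(p, q):
    """Great-circle distance from the 3-D chord (independent of haversine code)."""
    d = np.clip(np.dot(sphere_vec(*p), sphere_vec(*q)), -1.0, 1.0)
    return EARTH_R * np.arccos(d)


def oracle_bearing(p, q):
    """Forward azimuth from the great-circle tangent at p, CCW from east."""
    v1, v2 = sphere_vec(*p), sphere_vec(*q)
    t = v2 - np.dot(v1, v2) * v1  # tangent to the great circle at p
    lam, phi = np.radians(p[0]), np.radians(p[1])
    east = np.array([-np.sin(lam), np.cos(lam), 0.0])
    north = np.array([-np.sin(phi) * np.cos(lam), -np.sin(phi) * np.sin(lam),
                      np.cos(phi)])
    return np.arctan2(np.dot(t, north), np.dot(t, east))


# -- GridAxis / field construction -------------------------------------------


class TestGridAxis:
    def test_rejects_decreasing(self):
        with pytest.raises(ValueError, match="increasing"):
            GridAxis(np.array([1.0, 0.5]), "lon")

    def test_rejects_out_of_range_lat(self):
        with pytest.raises(ValueError):
            GridAxis(np.array([-95.0, 0.0]), "lat")

    def test_rejects_single_point(self):
        with pytest.raises(ValueError):
            GridAxis(np.array([1.0]), "lon")


class TestTimeGridField:
    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="inconsistent"):
            TimeGridField(GridAxis(np.array([0.0, 1.0]), "lon"),
                          GridAxis(np.array([0.0, 1.0]), "lat"),
                          np.array([0.0]), np.zeros((1, 3, 2)))

    def test_vector_component_check(self):
        with pytest.raises(ValueError):
            TimeGridField(GridAxis(np.array([0.0, 1.0]), "lon"),
                          GridAxis(np.array([0.0, 1.0]), "lat"),
                          np.array([0.0]), np.zeros((1, 2, 2, 3)))


# -- interpolate -------------------------------------------------------------


class TestInterpolate:
    def test_constant_field_identity(self):
        fld = constant_field([0.0, 1.0, 2.0], [50.0, 51.0], 7.25)
        assert interpolate(fld, Position(0.3, 50.9), 0.0) == pytest.approx(7.25)

    def test_bilinear_cell_centre(self, make_field):
        # corners 0,0,0,4 -> centre is the average, 1
        vals = np.array([[[0.0, 0.0], [0.0, 4.0]]])
        fld = make_field([0.0, 1.0], [50.0, 51.0], vals)
        assert interpolate(fld, Position(0.5, 50.5), 0.0) == pytest.approx(1.0)

    def test_exact_at_nodes(self, make_field, rng):
        vals = rng.normal(size=(1, 4, 5))
        lon = np.linspace(0, 2, 5)
        lat = np.linspace(50, 53, 4)
        fld = make_field(lon, lat, vals)
        for j in range(4):
            for i in range(5):
                assert interpolate(fld, Position(lon[i], lat[j]), 0.0) == \
                    pytest.approx(vals[0, j, i])

    def test_exact_at_time_slice(self, make_field):
        vals = np.array([np.full((2, 2), 1.0), np.full((2, 2), 3.0)])
        fld = make_field([0.0, 1.0], [50.0, 51.0], vals, times=(0.0, 2.0))
        assert fld.interp(0.5, 50.5, 0.0) == pytest.approx(1.0)
        assert fld.interp(0.5, 50.5, 2.0) == pytest.approx(3.0)
        assert fld.interp(0.5, 50.5, 1.0) == pytest.approx(2.0)

    def test_bounded_by_cell_values(self, make_field, rng):
        vals = rng.uniform(0, 10, size=(1, 3, 3))
        fld = make_field([0, 1, 2], [50, 51, 52], vals)
        for _ in range(50):
            p = Position(rng.uniform(0, 2), rng.uniform(50, 52))
            v = interpolate(fld, p, 0.0)
            assert vals.min() - 1e-12 <= v <= vals.max() + 1e-12

    def test_outside_grid_raises_named_error(self, make_field):
        fld = constant_field([0.0, 1.0], [50.0, 51.0], 0.0)
        with pytest.raises(DomainError, match="longitude"):
            interpolate(fld, Position(5.0, 50.5), 0.0)
        with pytest.raises(DomainError, match="latitude"):
            interpolate(fld, Position(0.5, 40.0), 0.0)

    def test_time_clamps_outside_range(self, make_field):
        vals = np.array([np.full((2, 2), 1.0), np.full((2, 2), 3.0)])
        fld = make_field([0.0, 1.0], [50.0, 51.0], vals, times=(0.0, 2.0))
        assert fld.interp(0.5, 50.5, -5.0) == pytest.approx(1.0)
        assert fld.interp(0.5, 50.5, 99.0) == pytest.approx(3.0)

    def test_vector_componentwise(self):
        fld = constant_field([0.0, 1.0], [50.0, 51.0], np.array([2.0, -1.0]))
        v = fld.interp(0.5, 50.5, 0.0)
        assert v == pytest.approx([2.0, -1.0])


# -- bearing -----------------------------------------------------------------


class TestBearing:
    def test_due_north(self):
        assert bearing(Position(5, 54), Position(5, 55)) == pytest.approx(np.pi / 2)

    def test_due_east(self):
        assert bearing(Position(5, 54), Position(6, 54)) == pytest.approx(0.0, abs=0.01)

    def test_coincident_raises(self):
        with pytest.raises(DegenerateBearingError):
            bearing(Position(5, 54), Position(5, 54))

    def test_matches_spherical_oracle(self, rng):
        for _ in range(300):
            p = (rng.uniform(-170, 170), rng.uniform(-80, 80))
            q = (p[0] + rng.uniform(-5, 5), p[1] + rng.uniform(-5, 5))
            if abs(q[0] - p[0]) < 1e-6 and abs(q[1] - p[1]) < 1e-6:
                continue
            got = bearing(Position(*p), Position(*q))
            want = oracle_bearing(p, q)
            assert abs(np.angle(np.exp(1j * (got - want)))) < 1e-6


# -- displace ----------------------------------------------------------------


class TestDisplace:
    def test_zero_distance(self):
        p = Position(3.0, 55.0)
        assert displace(p, 1.0, 0.0) == p

    def test_north_one_degree(self):
        # 111.19 km ~ 1 degree of latitude
        q = displace(Position(0.0, 0.0), np.pi / 2, 111.19)
        assert q.lat == pytest.approx(1.0, abs=1e-3)
        assert q.lon == pytest.approx(0.0, abs=1e-9)

    def test_distance_round_trip(self, rng):
        for _ in range(1000):
            p = (rng.uniform(-170, 170), rng.uniform(-70, 70))
            h = rng.uniform(-np.pi, np.pi)
            d = rng.uniform(0.1, 20.0)
            q = displace(Position(*p), h, d)
            assert oracle_distance_km(p, (q.lon, q.lat)) == pytest.approx(
                d, rel=1e-3)

    @settings(max_examples=50, deadline=None)
    @given(lat=st.floats(-60, 60), lon=st.floats(-170, 170),
           h=st.floats(-3.14, 3.14), a=st.floats(0.1, 10), b=st.floats(0.1, 10))
    def test_additivity(self, lat, lon, h, a, b):
        p = Position(lon, lat)
        q1 = displace(p, h, a + b)
        q2 = displace(displace(p, h, a), h, b)
        assert oracle_distance_km((q1.lon, q1.lat), (q2.lon, q2.lat)) < \
            1e-3 * (a + b)


# -- gradient directions -----------------------------------------------------


class TestGradientDirections:
    def test_depth_increasing_eastward(self, make_field):
        lon = np.linspace(0, 2, 9)
        lat = np.linspace(50, 52, 9)
        glon, _ = np.meshgrid(lon, lat)
        fld = make_field(lon, lat, (glon * 100.0)[None])
        h = deepest_water_direction(fld, Position(1.0, 51.0))
        assert h == pytest.approx(0.0, abs=1e-6)

    def test_flat_returns_none(self):
        fld = constant_field([0.0, 1.0, 2.0], [50.0, 51.0, 52.0], 100.0)
        assert deepest_water_direction(fld, Position(1.0, 51.0)) is None

    def test_radial_basin_points_to_centre(self, make_radial_field):
        lon = np.linspace(-2, 2, 41)
        lat = np.linspace(50, 54, 41)
        fld = make_radial_field(0.0, 52.0, 500.0, 0.2, lon, lat)
        # depth peaks at the basin centre; off-centre gradient points inward.
        # use points on the E/W axis where cos(lat) scaling cannot rotate it
        h = deepest_water_direction(fld, Position(1.0, 52.0))
        assert abs(np.angle(np.exp(1j * (h - np.pi)))) < 1e-3
        h = deepest_water_direction(fld, Position(-1.0, 52.0))
        assert abs(np.angle(np.exp(1j * h))) < 1e-3

    def test_noise_descent_flees_point_source(self, make_radial_field):
        lon = np.linspace(-2, 2, 41)
        lat = np.linspace(50, 54, 41)
        fld = make_radial_field(0.5, 52.0, 120.0, 0.5, lon, lat)
        h = noise_descent_direction(fld, Position(1.2, 52.0), 0.0)
        assert abs(np.angle(np.exp(1j * h))) < 1e-3  # due east, away

    def test_uniform_noise_returns_none(self):
        fld = constant_field([0.0, 1.0], [50.0, 51.0], 70.0)
        assert noise_descent_direction(fld, Position(0.5, 50.5), 0.0) is None

    def test_symmetric_sources_resolve_along_axis(self, make_field):
        # two equal bumps north and south of the query point: net descent is
        # east or west (along the symmetry axis), never meridional
        lon = np.linspace(-2, 2, 41)
        lat = np.linspace(50, 54, 41)
        glon, glat = np.meshgrid(lon, lat)
        vals = (np.exp(-((glon - 0.5) ** 2 + (glat - 52.5) ** 2))
                + np.exp(-((glon - 0.5) ** 2 + (glat - 51.5) ** 2)))
        fld = make_field(lon, lat, vals[None])
        h = noise_descent_direction(fld, Position(0.0, 52.0), 0.0)
        assert abs(np.sin(h)) < 1e-6
        assert np.cos(h) == pytest.approx(-1.0, abs=1e-6)  # away = west


# -- land mask ---------------------------------------------------------------


class TestLandMask:
    def test_from_depth(self, make_field):
        vals = np.array([[[10.0, -5.0], [20.0, 30.0]]])
        fld = make_field([0.0, 1.0], [50.0, 51.0], vals)
        mask = LandMask.from_depth(fld)
        assert bool(mask.is_land(1.0, 50.0)[0]) is True
        assert bool(mask.is_land(0.0, 50.0)[0]) is False

    def test_outside_grid_is_land(self, make_field):
        fld = constant_field([0.0, 1.0], [50.0, 51.0], 100.0)
        mask = LandMask.from_depth(fld)
        assert bool(mask.is_land(10.0, 50.5)[0]) is True


# -- IO round trips ----------------------------------------------------------


class TestIO:
    def test_netcdf_round_trip(self, tmp_path, make_field, rng):
        vals = rng.normal(size=(2, 3, 4))
        fld = make_field(np.linspace(0, 3, 4), np.linspace(50, 52, 3),
                         vals, times=(0.0, 24.0), units="dB")
        to_netcdf(fld, tmp_path / "f.nc")
        back = from_netcdf(tmp_path / "f.nc")
        np.testing.assert_allclose(back.values, vals)
        assert back.units == "dB"

    def test_csv_round_trip_scalar(self, tmp_path, make_field, rng):
        vals = rng.normal(size=(2, 3, 4))
        fld = make_field(np.linspace(0, 3, 4), np.linspace(50, 52, 3),
                         vals, times=(0.0, 24.0))
        to_csv(fld, tmp_path / "f.csv")
        back = from_csv(tmp_path / "f.csv")
        np.testing.assert_allclose(back.values, vals)
        np.testing.assert_allclose(back.times, [0.0, 24.0])

    def test_csv_round_trip_vector(self, tmp_path, rng):
        fld = constant_field([0.0, 1.0], [50.0, 51.0], np.array([1.5, -0.5]))
        to_csv(fld, tmp_path / "v.csv")
        back = from_csv(tmp_path / "v.csv")
        assert back.is_vector
        np.testing.assert_allclose(back.values, fld.values)
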