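"""Gridded environmental layers and geographic primitives.

Layers (ambient noise, currents, bathymetry) live on regular lon/lat grids
with an optional time axis (hours since simulation start).  Queries use
bilinear interpolation in space and linear interpolation in time.

Conventions shared by the whole package:

* headings are radians counter-clockwise from local east;
* positions are degrees (lon, lat);
* distances are km, depths are metres (positive = water depth);
* noise levels are dB re 1 uPa at 1 m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0  # ~111.195 km per degree of latitude

#: gradients with magnitude below this (field units per km) count as flat
GRADIENT_TOL = 1e-9


class DomainError(ValueError):
    """A query fell outside the spatial support of a gridded field."""


class DegenerateBearingError(ValueError):
    """Bearing requested between coincident points."""


@dataclass(frozen=True)
class Position:
    """A geographic point in degrees."""

    lon: float
    lat: float

    def __iter__(self):
        yield self.lon
        yield self.lat


@dataclass(frozen=True)
class GridAxis:
    """Strictly increasing 1-D coordinate axis in degrees."""

    coordinates: np.ndarray
    kind: str = "lon"  # "lon" or "lat"

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if coords.ndim != 1 or coords.size < 2:
            raise ValueError("axis needs at least two coordinates")
        if not np.all(np.diff(coords) > 0):
            raise ValueError(f"{self.kind} axis must be strictly increasing")
        lo, hi = (-180.0, 180.0) if self.kind == "lon" else (-90.0, 90.0)
        if coords[0] < lo or coords[-1] > hi:
            raise ValueError(f"{self.kind} axis outside [{lo}, {hi}]")

    def __len__(self) -> int:
        return self.coordinates.size

    @property
    def spacing(self) -> float:
        return float(np.median(np.diff(self.coordinates)))


def _cell_index(axis: np.ndarray, x: np.ndarray):
    i = np.clip(np.searchsorted(axis, x, side="right") - 1, 0, axis.size - 2)
    frac = (x - axis[i]) / (axis[i + 1] - axis[i])
    return i, frac


@dataclass
class TimeGridField:
    """Time-stamped gridded scalar or 2-vector layer.

    ``values`` is indexed ``(time, lat, lon)`` for scalars and
    ``(time, lat, lon, 2)`` for vectors (east, north components).
    Static layers carry a single time slice.
    """

    lon: GridAxis
    lat: GridAxis
    times: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        expected = (self.times.size, len(self.lat), len(self.lon))
        if self.values.shape[:3] != expected:
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with axes {expected}"
            )
        if self.values.ndim == 4 and self.values.shape[3] != 2:
            raise ValueError("vector fields must have 2 components")
        if self.values.ndim not in (3, 4):
            raise ValueError("values must be (t, lat, lon) or (t, lat, lon, 2)")
        self._warned_time_clamp = False

    # -- queries ---------------------------------------------------------

    @property
    def is_vector(self) -> bool:
        return self.values.ndim == 4

    @property
    def bbox(self):
        return (
            float(self.lon.coordinates[0]),
            float(self.lon.coordinates[-1]),
            float(self.lat.coordinates[0]),
            float(self.lat.coordinates[-1]),
        )

    def contains(self, lon, lat) -> np.ndarray:
        w, e, s, n = self.bbox
        return (np.asarray(lon) >= w) & (np.asarray(lon) <= e) & \
            (np.asarray(lat) >= s) & (np.asarray(lat) <= n)

    def _check_domain(self, lon: np.ndarray, lat: np.ndarray) -> None:
        w, e, s, n = self.bbox
        if np.any((lon < w) | (lon > e)):
            bad = float(np.asarray(lon).ravel()[np.argmax((lon < w) | (lon > e))])
            raise DomainError(f"longitude {bad} outside grid range [{w}, {e}]")
        if np.any((lat < s) | (lat > n)):
            bad = float(np.asarray(lat).ravel()[np.argmax((lat < s) | (lat > n))])
            raise DomainError(f"latitude {bad} outside grid range [{s}, {n}]")

    def _time_slice(self, t: float) -> np.ndarray:
        """Time-interpolated (lat, lon[, 2]) slab; clamps outside the range."""
        times = self.times
        if times.size == 1:
            return self.values[0]
        if t < times[0] or t > times[-1]:
            if not self._warned_time_clamp:
                logger.warning(
                    "time %.3f h outside field range [%.3f, %.3f]; clamping",
                    t, times[0], times[-1],
                )
                self._warned_time_clamp = True
            t = float(np.clip(t, times[0], times[-1]))
        k = int(np.clip(np.searchsorted(times, t, side="right") - 1, 0, times.size - 2))
        w = (t - times[k]) / (times[k + 1] - times[k])
        if w == 0.0:
            return self.values[k]
        return (1.0 - w) * self.values[k] + w * self.values[k + 1]

    def interp(self, lon, lat, t: float) -> np.ndarray:
        """Bilinear space / linear time interpolation; accepts array queries."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        scalar = lon.ndim == 0 and lat.ndim == 0
        lon, lat = np.atleast_1d(lon), np.atleast_1d(lat)
        self._check_domain(lon, lat)
        slab = self._time_slice(float(t))
        i, fx = _cell_index(self.lon.coordinates, lon)
        j, fy = _cell_index(self.lat.coordinates, lat)
        if slab.ndim == 3:  # broadcast weights across the component axis
            fx, fy = fx[..., None], fy[..., None]
        v00 = slab[j, i]
        v01 = slab[j, i + 1]
        v10 = slab[j + 1, i]
        v11 = slab[j + 1, i + 1]
        out = (1 - fy) * ((1 - fx) * v00 + fx * v01) + fy * ((1 - fx) * v10 + fx * v11)
        if scalar:
            return out[0] if slab.ndim == 3 else float(out[0])
        return out


@dataclass
class LandMask:
    """Boolean land grid on the same axes as a depth field (True = land)."""

    lon: GridAxis
    lat: GridAxis
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (len(self.lat), len(self.lon)):
            raise ValueError("mask shape inconsistent with axes")

    @classmethod
    def from_depth(cls, depth: TimeGridField, threshold: float = 0.0) -> "LandMask":
        return cls(depth.lon, depth.lat, depth.values[0] <= threshold)

    def is_land(self, lon, lat) -> np.ndarray:
        """Nearest-cell land lookup; out-of-grid queries count as land."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lons, lats = self.lon.coordinates, self.lat.coordinates
        outside = (lon < lons[0]) | (lon > lons[-1]) | (lat < lats[0]) | (lat > lats[-1])
        i = np.clip(np.searchsorted(lons, lon) , 0, lons.size - 1)
        i = np.where((i > 0) & (np.abs(lon - lons[np.maximum(i - 1, 0)]) <
                                np.abs(lons[np.minimum(i, lons.size - 1)] - lon)), i - 1, i)
        j = np.clip(np.searchsorted(lats, lat), 0, lats.size - 1)
        j = np.where((j > 0) & (np.abs(lat - lats[np.maximum(j - 1, 0)]) <
                                np.abs(lats[np.minimum(j, lats.size - 1)] - lat)), j - 1, j)
        return self.mask[j, i] | outside


# -- module-level operations -------------------------------------------------


def interpolate(field: TimeGridField, p: Position, t: float):
    """Value of ``field`` at position ``p`` and time ``t`` (hours)."""
    return field.interp(p.lon, p.lat, t)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km; fully vectorized."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def distance_km(a: Position, b: Position) -> float:
    return float(haversine_km(a.lon, a.lat, b.lon, b.lat))


def wrap_angle(theta):
    """Wrap to (-pi, pi]."""
    out = np.mod(np.asarray(theta) + np.pi, 2 * np.pi) - np.pi
    return np.where(out == -np.pi, np.pi, out)


def bearing(frm: Position, to: Position) -> float:
    """Initial great-circle bearing, radians counter-clockwise from east."""
    if frm.lon == to.lon and frm.lat == to.lat:
        raise DegenerateBearingError("bearing undefined between coincident points")
    phi1, phi2 = np.radians(frm.lat), np.radians(to.lat)
    dlam = np.radians(to.lon - frm.lon)
    x = np.sin(dlam) * np.cos(phi2)
    y = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    azimuth = np.arctan2(x, y)  # clockwise from north
    return float(wrap_angle(np.pi / 2 - azimuth))


def displace(p: Position, heading: float, dist_km: float) -> Position:
    """Move ``dist_km`` along ``heading`` on the local tangent plane.

    Uses equirectangular scaling with the longitude metric evaluated at the
    midpoint latitude; accurate to well under 0.1% for steps up to ~20 km.
    """
    if dist_km < 0:
        raise ValueError("distance must be non-negative")
    if dist_km == 0:
        return p
    dlat = dist_km * np.sin(heading) / KM_PER_DEG
    lat_mid = np.radians(p.lat + dlat / 2.0)
    dlon = dist_km * np.cos(heading) / (KM_PER_DEG * np.cos(lat_mid))
    return Position(float(p.lon + dlon), float(p.lat + dlat))


def displace_many(lon: np.ndarray, lat: np.ndarray, heading: np.ndarray,
                  dist_km) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`displace` for per-agent stepping."""
    dist_km = np.asarray(dist_km, dtype=float)
    dlat = dist_km * np.sin(heading) / KM_PER_DEG
    lat_mid = np.radians(lat + dlat / 2.0)
    dlon = dist_km * np.cos(heading) / (KM_PER_DEG * np.cos(lat_mid))
    return lon + dlon, lat + dlat


def _planar_gradient(fld: TimeGridField, p: Position, t: float):
    """Central-difference gradient (per km, east/north) of the interpolated surface."""
    w, e, s, n = fld.bbox
    dlon = fld.lon.spacing
    dlat = fld.lat.spacing
    xw, xe = max(p.lon - dlon, w), min(p.lon + dlon, e)
    ys, yn = max(p.lat - dlat, s), min(p.lat + dlat, n)
    fw = fld.interp(xw, p.lat, t)
    fe = fld.interp(xe, p.lat, t)
    fs = fld.interp(p.lon, ys, t)
    fn = fld.interp(p.lon, yn, t)
    dx_km = (xe - xw) * KM_PER_DEG * np.cos(np.radians(p.lat))
    dy_km = (yn - ys) * KM_PER_DEG
    return (fe - fw) / dx_km, (fn - fs) / dy_km


def deepest_water_direction(depth: TimeGridField, p: Position,
                            t: float = 0.0) -> float | None:
    """Heading of steepest depth increase, or None on flat bathymetry."""
    gx, gy = _planar_gradient(depth, p, t)
    if np.hypot(gx, gy) < GRADIENT_TOL:
        return None
    return float(np.arctan2(gy, gx))


def noise_descent_direction(noise: TimeGridField, p: Position,
                            t: float) -> float | None:
    """Heading of steepest noise decrease (negative phonotaxis), or None."""
    gx, gy = _planar_gradient(noise, p, t)
    if np.hypot(gx, gy) < GRADIENT_TOL:
        return None
    return float(np.arctan2(-gy, -gx))


# -- IO ----------------------------------------------------------------------


def to_netcdf(fld: TimeGridField, path, name: str = "value") -> None:
    """Write a field as a CF-style NetCDF file (scipy backend, NetCDF3)."""
    import xarray as xr

    if fld.is_vector:
        ds = xr.Dataset(
            {
                f"{name}_east": (("time", "lat", "lon"), fld.values[..., 0]),
                f"{name}_north": (("time", "lat", "lon"), fld.values[..., 1]),
            },
            coords={"time": fld.times, "lat": fld.lat.coordinates,
                    "lon": fld.lon.coordinates},
        )
    else:
        ds = xr.Dataset(
            {name: (("time", "lat", "lon"), fld.values)},
            coords={"time": fld.times, "lat": fld.lat.coordinates,
                    "lon": fld.lon.coordinates},
        )
    ds.attrs["units"] = fld.units
    ds.time.attrs["long_name"] = "hours since simulation start"
    ds.to_netcdf(path, engine="scipy")


def from_netcdf(path, name: str = "value") -> TimeGridField:
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        lon = GridAxis(ds.lon.values, "lon")
        lat = GridAxis(ds.lat.values, "lat")
        times = ds.time.values.astype(float)
        if name in ds:
            values = ds[name].values
        else:
            values = np.stack(
                [ds[f"{name}_east"].values, ds[f"{name}_north"].values], axis=-1
            )
        units = str(ds.attrs.get("units", ""))
    return TimeGridField(lon, lat, times, values, units)


def to_csv(fld: TimeGridField, path) -> None:
    """Long-format CSV fallback (time,lat,lon,value[,value2]) for text fixtures."""
    import pandas as pd

    tt, yy, xx = np.meshgrid(fld.times, fld.lat.coordinates,
                             fld.lon.coordinates, indexing="ij")
    cols = {"time": tt.ravel(), "lat": yy.ravel(), "lon": xx.ravel()}
    if fld.is_vector:
        cols["value_east"] = fld.values[..., 0].ravel()
        cols["value_north"] = fld.values[..., 1].ravel()
    else:
        cols["value"] = fld.values.ravel()
    pd.DataFrame(cols).to_csv(path, index=False)


def from_csv(path, units: str = "") -> TimeGridField:
    import pandas as pd

    df = pd.read_csv(path)
    times = np.unique(df["time"].to_numpy(float))
    lats = np.unique(df["lat"].to_numpy(float))
    lons = np.unique(df["lon"].to_numpy(float))
    shape = (times.size, lats.size, lons.size)
    df = df.sort_values(["time", "lat", "lon"])
    if "value_east" in df.columns:
        values = np.stack(
            [df["value_east"].to_numpy(float).reshape(shape),
             df["value_north"].to_numpy(float).reshape(shape)], axis=-1)
    else:
        values = df["value"].to_numpy(float).reshape(shape)
    return TimeGridField(GridAxis(lons, "lon"), GridAxis(lats, "lat"),
                         times, values, units)


def constant_field(lon: Sequence[float], lat: Sequence[float], value,
                   times: Sequence[float] = (0.0,), units: str = "") -> TimeGridField:
    """Convenience constructor for uniform scalar/vector layers."""
    lon_ax, lat_ax = GridAxis(np.asarray(lon), "lon"), GridAxis(np.asarray(lat), "lat")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    value = np.asarray(value, dtype=float)
    if value.ndim == 0:
        vals = np.full((times.size, len(lat_ax), len(lon_ax)), float(value))
    else:
        vals = np.broadcast_to(
            value, (times.size, len(lat_ax), len(lon_ax), 2)).copy()
    return TimeGridField(lon_ax, lat_ax, times, vals, units)
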