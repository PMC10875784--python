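"""Sound transmission, call detection, and synthetic noise-map rendering.

Received level follows a log-range transmission-loss law
``RL = SL - gamma * log10(r)`` with r in metres and a 1 m reference
distance.  A call is detectable when both the signal-to-noise ratio at the
receiver and the absolute received level clear their thresholds.
Multiple incoherent sources combine by power summation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .environment import GridAxis, TimeGridField, haversine_km

MIN_RANGE_M = 1.0  # reference distance of the source level


@dataclass(frozen=True)
class AcousticParams:
    """Call emission and detection parameters."""

    source_level: float = 178.0   # dB re 1 uPa at 1 m
    gamma: float = 17.8           # spreading coefficient, 10 (cylindrical) .. 20 (spherical)
    snr_min: float = -5.0         # dB, minimum signal-to-noise ratio
    rl_min: float = 88.0          # dB, minimum received level

    def __post_init__(self):
        if not 10.0 <= self.gamma <= 20.0:
            raise ValueError("gamma must lie in [10, 20]")
        if self.source_level <= self.rl_min:
            raise ValueError("source level must exceed the minimum received level")


@dataclass
class NoiseSource:
    """A fixed or mobile acoustic source with a daily activity schedule.

    Mobile sources carry a waypoint trajectory ``[(t_hours, lon, lat), ...]``
    with strictly increasing times and move piecewise-linearly between
    waypoints (clamped to the first/last waypoint outside the time span).
    ``active_hours`` lists daily on-windows ``[(start, end), ...]`` in [0, 24];
    an empty list means always on.
    """

    source_level: float
    kind: str = "fixed"
    position: tuple[float, float] | None = None          # fixed: (lon, lat)
    waypoints: Sequence[tuple[float, float, float]] = ()  # mobile: (t, lon, lat)
    active_hours: Sequence[tuple[float, float]] = ()

    def __post_init__(self):
        if self.kind not in ("fixed", "mobile"):
            raise ValueError("kind must be 'fixed' or 'mobile'")
        if self.kind == "fixed" and self.position is None:
            raise ValueError("fixed source needs a position")
        if self.kind == "mobile":
            wt = np.asarray([w[0] for w in self.waypoints], dtype=float)
            if wt.size < 2 or not np.all(np.diff(wt) > 0):
                raise ValueError("mobile source needs >= 2 waypoints with "
                                 "strictly increasing times")
        for lo, hi in self.active_hours:
            if not (0.0 <= lo <= 24.0 and 0.0 <= hi <= 24.0):
                raise ValueError("active hours must lie within [0, 24]")

    def is_active(self, t: float) -> bool:
        if not self.active_hours:
            return True
        hod = t % 24.0
        return any(lo <= hod < hi for lo, hi in self.active_hours)

    def position_at(self, t: float) -> tuple[float, float]:
        if self.kind == "fixed":
            return self.position  # type: ignore[return-value]
        wt = np.asarray([w[0] for w in self.waypoints], dtype=float)
        lons = np.asarray([w[1] for w in self.waypoints], dtype=float)
        lats = np.asarray([w[2] for w in self.waypoints], dtype=float)
        return (float(np.interp(t, wt, lons)), float(np.interp(t, wt, lats)))


def received_level(source_level: float, r_m, gamma: float):
    """Received level in dB at range ``r_m`` metres; ranges below 1 m clamp."""
    r = np.maximum(np.asarray(r_m, dtype=float), MIN_RANGE_M)
    out = source_level - gamma * np.log10(r)
    return float(out) if out.ndim == 0 else out


def is_detectable(source_level: float, r_m, noise_at_receiver,
                  params: AcousticParams):
    """True where SNR >= snr_min and RL >= rl_min (both inclusive)."""
    rl = received_level(source_level, r_m, params.gamma)
    out = (rl - np.asarray(noise_at_receiver) >= params.snr_min) & (rl >= params.rl_min)
    return bool(out) if np.ndim(out) == 0 else out


def detection_range(noise: float, params: AcousticParams) -> float:
    """Maximum detectable range in km for ambient noise ``noise`` dB.

    Whichever of the SNR criterion and the received-level floor binds first
    sets the range; very low noise hits the floor, giving a noise-independent
    pristine plateau.
    """
    limit = max(noise + params.snr_min, params.rl_min)
    r_m = 10.0 ** ((params.source_level - limit) / params.gamma)
    return max(r_m, MIN_RANGE_M) / 1000.0


def combine_levels(levels) -> float:
    """Incoherent (power) sum of dB levels: 10 log10 sum 10^(L/10)."""
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("cannot combine an empty list of levels")
    return float(10.0 * np.log10(np.sum(10.0 ** (levels / 10.0), axis=0)))


def _power_sum(level_stack: np.ndarray) -> np.ndarray:
    return 10.0 * np.log10(np.sum(10.0 ** (level_stack / 10.0), axis=0))


def render_noise_map(sources: Sequence[NoiseSource], wind_floor: TimeGridField,
                     times: Sequence[float] | None = None, gamma: float = 17.8,
                     slowdown_zones: Sequence[tuple] = ()) -> TimeGridField:
    """Synthesize an ambient-noise field from a wind floor plus point sources.

    At every grid node and time, active sources contribute their received
    level (mobile positions interpolated along waypoints) and everything is
    combined by power summation with the wind floor.  ``slowdown_zones`` is a
    list of ``(shapely_polygon, dB_reduction)`` pairs; a mobile source inside
    a zone has its source level reduced by that amount.
    """
    if times is None:
        times = wind_floor.times
    times = np.atleast_1d(np.asarray(times, dtype=float))
    lons = wind_floor.lon.coordinates
    lats = wind_floor.lat.coordinates
    glon, glat = np.meshgrid(lons, lats)  # (nlat, nlon)
    out = np.empty((times.size, lats.size, lons.size))
    for k, t in enumerate(times):
        layers = [wind_floor._time_slice(float(t))]
        for src in sources:
            if not src.is_active(float(t)):
                continue
            slon, slat = src.position_at(float(t))
            sl = src.source_level
            if slowdown_zones:
                from shapely.geometry import Point

                pt = Point(slon, slat)
                for zone, reduction in slowdown_zones:
                    if zone.contains(pt):
                        sl = sl - reduction
                        break
            r_m = haversine_km(glon, glat, slon, slat) * 1000.0
            layers.append(received_level(sl, r_m, gamma))
        out[k] = _power_sum(np.stack(layers))
    return TimeGridField(wind_floor.lon, wind_floor.lat, times, out,
                         units="dB re 1 uPa")
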