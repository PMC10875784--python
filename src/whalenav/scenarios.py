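"""Scenario presets and synthetic environment generation.

Real ocean layers (currents, bathymetry, soundmaps) are not bundled; every
preset instead runs on generated stand-ins: an idealized sea with a wind
noise floor, optional vessel lanes, fixed construction sources with daily
duty cycles, and simple bathymetry features (open sea, island, strait,
basin, coastal ramp).

Environment *recipes* are plain dicts so scenario configs stay serializable;
:func:`build_environment` turns a recipe into gridded layers.
"""

from __future__ import annotations

import copy

import numpy as np

from .acoustics import NoiseSource, render_noise_map
from .environment import (
    GridAxis,
    LandMask,
    TimeGridField,
    constant_field,
    haversine_km,
)
from .simulator import ConfigError, EnvironmentBundle, ScenarioConfig

# -- synthetic bathymetry ----------------------------------------------------


def _depth_grid(depth_spec: dict, glon: np.ndarray, glat: np.ndarray) -> np.ndarray:
    kind = depth_spec.get("kind", "open")
    base = float(depth_spec.get("base_depth_m", 100.0))
    if kind == "open":
        return np.full(glon.shape, base)
    if kind == "island":
        lon0, lat0 = depth_spec["centre"]
        sigma = float(depth_spec.get("radius_deg", 0.5))
        peak = float(depth_spec.get("peak_m", base * 2))
        r2 = (glon - lon0) ** 2 + (glat - lat0) ** 2
        return base - peak * np.exp(-r2 / (2 * sigma ** 2))
    if kind == "basin":
        lon0, lat0 = depth_spec["centre"]
        sigma = float(depth_spec.get("radius_deg", 2.0))
        extra = float(depth_spec.get("extra_depth_m", 400.0))
        r2 = (glon - lon0) ** 2 + (glat - lat0) ** 2
        return base + extra * np.exp(-r2 / (2 * sigma ** 2))
    if kind == "strait":
        # east-west land wall with a north-south channel through it; the
        # channel floor is deepest on its centreline
        wall_s, wall_n = depth_spec["wall_lat"]
        ch_w, ch_e = depth_spec["channel_lon"]
        depth = np.full(glon.shape, base)
        in_wall = (glat >= wall_s) & (glat <= wall_n)
        depth[in_wall] = -10.0
        in_channel = in_wall & (glon >= ch_w) & (glon <= ch_e)
        mid = 0.5 * (ch_w + ch_e)
        half = 0.5 * (ch_e - ch_w)
        profile = 1.0 - ((glon[in_channel] - mid) / half) ** 2
        depth[in_channel] = base * np.maximum(profile, 0.05)
        return depth
    if kind == "coast":
        # land south of coast_lat, depth ramping up northward
        coast_lat = float(depth_spec.get("coast_lat", 53.0))
        ramp = float(depth_spec.get("ramp_m_per_deg", 100.0))
        return (glat - coast_lat) * ramp
    raise ConfigError(f"unknown depth kind {kind!r}")


def _current_field(cur_spec: dict, lon_ax: GridAxis,
                   lat_ax: GridAxis) -> TimeGridField | None:
    kind = cur_spec.get("kind", "none")
    if kind == "none":
        return None
    if kind == "uniform":
        u, v = cur_spec.get("east_kmh", 0.0), cur_spec.get("north_kmh", 0.0)
        return constant_field(lon_ax.coordinates, lat_ax.coordinates,
                              np.array([u, v]), units="km/h")
    raise ConfigError(f"unknown current kind {kind!r}")


def _shuttle_waypoints(start, end, speed_kmh, duration_h, phase=0.0):
    """Back-and-forth vessel waypoints along a lane until ``duration_h``."""
    leg_km = float(haversine_km(start[0], start[1], end[0], end[1]))
    leg_h = max(leg_km / speed_kmh, 1e-6)
    way, t, k = [], -phase * 2 * leg_h, 0
    while t <= duration_h + leg_h or len(way) < 2:
        p = start if k % 2 == 0 else end
        way.append((t, float(p[0]), float(p[1])))
        t += leg_h
        k += 1
    return way


def expand_sources(source_specs, duration_h: float) -> list[NoiseSource]:
    """Turn recipe source dicts (fixed / mobile / lane) into NoiseSources."""
    out: list[NoiseSource] = []
    for spec in source_specs:
        kind = spec.get("kind", "fixed")
        if kind == "fixed":
            out.append(NoiseSource(
                source_level=float(spec["source_level"]), kind="fixed",
                position=tuple(spec["position"]),
                active_hours=[tuple(w) for w in spec.get("active_hours", [])]))
        elif kind == "mobile":
            out.append(NoiseSource(
                source_level=float(spec["source_level"]), kind="mobile",
                waypoints=[tuple(w) for w in spec["waypoints"]],
                active_hours=[tuple(w) for w in spec.get("active_hours", [])]))
        elif kind == "lane":
            n = int(spec.get("n_vessels", 2))
            for i in range(n):
                out.append(NoiseSource(
                    source_level=float(spec.get("source_level", 185.0)),
                    kind="mobile",
                    waypoints=_shuttle_waypoints(
                        spec["start"], spec["end"],
                        float(spec.get("speed_kmh", 20.0)),
                        duration_h, phase=i / max(n, 1))))
        else:
            raise ConfigError(f"unknown source kind {kind!r}")
    return out


def make_synthetic_sea(recipe: dict) -> EnvironmentBundle:
    """Bathymetry, land mask, currents and wind noise floor from a recipe.

    The returned noise layer is the wind floor only; point sources are added
    by :func:`build_environment` / :func:`whalenav.acoustics.render_noise_map`.
    """
    extent = recipe.get("extent")
    if extent is None:
        raise ConfigError("recipe needs an 'extent' [W, E, S, N]")
    w, e, s, n = (float(v) for v in extent)
    if not (w < e and s < n):
        raise ConfigError(f"inconsistent extent {extent}")
    res = float(recipe.get("resolution_deg", 0.5))
    lon_ax = GridAxis(np.arange(w, e + res / 2, res), "lon")
    lat_ax = GridAxis(np.arange(s, n + res / 2, res), "lat")
    glon, glat = np.meshgrid(lon_ax.coordinates, lat_ax.coordinates)
    depth_vals = _depth_grid(recipe.get("depth", {"kind": "open"}), glon, glat)
    depth = TimeGridField(lon_ax, lat_ax, np.array([0.0]),
                          depth_vals[None], units="m")
    land = LandMask.from_depth(depth)
    wind = constant_field(lon_ax.coordinates, lat_ax.coordinates,
                          float(recipe.get("wind_floor_db", 55.0)), units="dB")
    current = _current_field(recipe.get("current", {"kind": "none"}),
                             lon_ax, lat_ax)
    return EnvironmentBundle(noise=wind, current=current, depth=depth, land=land)


def build_environment(recipe: dict, duration_h: float = 744.0) -> EnvironmentBundle:
    """Full environment: synthetic sea plus rendered ambient-noise map."""
    bundle = make_synthetic_sea(recipe)
    sources = expand_sources(recipe.get("noise_sources", []), duration_h)
    zones = []
    for z in recipe.get("slowdown_zones", []):
        from shapely.geometry import box

        zw, ze, zs, zn = z["box"]
        zones.append((box(zw, zs, ze, zn), float(z.get("reduction_db", 10.0))))
    if sources:
        dt_noise = float(recipe.get("noise_time_step_h", 1.0))
        times = np.arange(0.0, duration_h + dt_noise / 2, dt_noise)
        bundle.noise = render_noise_map(sources, bundle.noise, times,
                                        gamma=float(recipe.get("gamma", 17.8)),
                                        slowdown_zones=zones)
    return bundle


# -- preset library ----------------------------------------------------------

_BASE_RECIPE = {
    "extent": [-8.0, 8.0, 52.0, 62.5],
    "resolution_deg": 0.5,
    "depth": {"kind": "open", "base_depth_m": 100.0},
    "current": {"kind": "none"},
    "wind_floor_db": 55.0,
    "noise_sources": [],
}

_LANES = [
    {"kind": "lane", "start": [-7.5, 55.0], "end": [7.5, 55.5],
     "n_vessels": 2, "speed_kmh": 20.0, "source_level": 185.0},
    {"kind": "lane", "start": [-7.5, 57.5], "end": [7.5, 57.0],
     "n_vessels": 2, "speed_kmh": 20.0, "source_level": 185.0},
    {"kind": "lane", "start": [0.0, 52.5], "end": [-4.0, 62.0],
     "n_vessels": 2, "speed_kmh": 20.0, "source_level": 185.0},
]

PRESETS = ("pristine", "current_synthetic", "avoidance_sweep", "info_loss",
           "traffic_increase", "slowdown", "construction")


def _base_config(**kw) -> ScenarioConfig:
    kw.setdefault("environment", copy.deepcopy(_BASE_RECIPE))
    return ScenarioConfig(**kw)


def _with_lanes(recipe: dict, factor: float = 1.0) -> dict:
    recipe = copy.deepcopy(recipe)
    lanes = copy.deepcopy(_LANES)
    for lane in lanes:
        lane["n_vessels"] = int(round(lane["n_vessels"] * factor))
    recipe["noise_sources"] = lanes
    return recipe


def build_scenario(preset: str, overrides: dict | None = None):
    """Resolve a named preset into ScenarioConfig(s), overrides applied last.

    Sweep presets (avoidance_sweep, info_loss, construction) return a list
    of configs, one per swept parameter value; others return a single config.
    """
    from .navigation import InfoLossParams, NoiseResponseParams

    if preset == "pristine":
        cfg = _base_config(
            noise_response=NoiseResponseParams(threshold_db=120.0))
    elif preset == "current_synthetic":
        cfg = _base_config(
            noise_response=NoiseResponseParams(threshold_db=120.0),
            environment=_with_lanes(_BASE_RECIPE))
    elif preset == "avoidance_sweep":
        cfg = [
            _base_config(noise_response=NoiseResponseParams(threshold_db=th),
                         environment=_with_lanes(_BASE_RECIPE))
            for th in (105.0, 110.0, 115.0)
        ]
    elif preset == "info_loss":
        cfg = [
            _base_config(
                noise_response=NoiseResponseParams(threshold_db=120.0),
                info_loss=InfoLossParams(enabled=True, kappa_min=0.0,
                                         threshold_db=nil),
                environment=_with_lanes(_BASE_RECIPE))
            for nil in (110.0, 100.0)
        ]
    elif preset == "traffic_increase":
        cfg = _base_config(
            start_box=(4.5, 5.5, 55.0, 56.0),
            noise_response=NoiseResponseParams(threshold_db=115.0),
            environment=_with_lanes(_BASE_RECIPE, factor=1.5))
    elif preset == "slowdown":
        recipe = _with_lanes(_BASE_RECIPE)
        recipe["slowdown_zones"] = [
            {"box": [-3.0, 3.0, 54.5, 58.0], "reduction_db": 10.0}]
        cfg = _base_config(
            start_box=(4.5, 5.5, 55.0, 56.0),
            noise_response=NoiseResponseParams(threshold_db=115.0),
            environment=recipe)
    elif preset == "construction":
        cfgs = []
        for hours in (0, 5, 8, 12):
            recipe = copy.deepcopy(_BASE_RECIPE)
            if hours > 0:
                recipe["noise_sources"] = [
                    {"kind": "fixed", "position": [-1.5, 58.0],
                     "source_level": 210.0,
                     "active_hours": [[0.0, float(hours)]]}]
            cfgs.append(_base_config(
                noise_response=NoiseResponseParams(threshold_db=115.0),
                environment=recipe))
        cfg = cfgs
    else:
        raise ConfigError(
            f"unknown preset {preset!r}; valid presets: {', '.join(PRESETS)}")

    if overrides:
        configs = cfg if isinstance(cfg, list) else [cfg]
        configs = [_apply_overrides(c, overrides) for c in configs]
        cfg = configs if isinstance(cfg, list) else configs[0]
    return cfg


def _apply_overrides(cfg: ScenarioConfig, overrides: dict) -> ScenarioConfig:
    d = cfg.to_dict()
    if isinstance(cfg.environment, dict):
        d["environment"] = copy.deepcopy(cfg.environment)
    for key, value in overrides.items():
        head, _, rest = key.partition(".")
        if head not in d:
            raise ConfigError(
                f"unknown parameter {key!r}; valid: {', '.join(sorted(d))}")
        if rest:
            node = d[head]
            parts = rest.split(".")
            for p in parts[:-1]:
                node = node[p]
            if parts[-1] not in node:
                raise ConfigError(f"unknown parameter {key!r}")
            node[parts[-1]] = value
        else:
            d[head] = value
    return ScenarioConfig.from_dict(d)
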