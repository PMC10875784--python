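"""Ensemble trajectory metrics.

Four summaries of a set of simulation repeats: a median trajectory built by
intersection switching (always a concatenation of pieces of real tracks), a
binned occupancy spread region, arrivals over time, mean population distance
to target, and the daily mean number of detectable conspecifics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import KM_PER_DEG, haversine_km
from .simulator import ScenarioConfig, TrajectorySet


@dataclass
class TimeSeries:
    """A per-time metric with across-repeat mean and standard deviation."""

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    per_repeat: np.ndarray  # (n_repeats, nt)

    def to_dict(self) -> dict:
        return {"times": self.times.tolist(), "mean": self.mean.tolist(),
                "sd": self.sd.tolist()}


@dataclass
class MedianTrajectory:
    vertices: np.ndarray                       # (m, 2) lon/lat
    provenance: list[tuple[int, tuple[int, int]]]  # (agent id, segment span)


@dataclass
class SpreadRegion:
    lon_edges: np.ndarray
    lat_edges: np.ndarray
    frequency: np.ndarray   # (nlat_bins, nlon_bins), sums to 1
    threshold: float
    boundary: np.ndarray    # boolean mask of bins >= threshold

    def to_geojson(self) -> dict:
        """Union of the above-threshold bins as a (Multi)Polygon feature."""
        from shapely.geometry import box, mapping
        from shapely.ops import unary_union

        cells = [
            box(self.lon_edges[i], self.lat_edges[j],
                self.lon_edges[i + 1], self.lat_edges[j + 1])
            for j, i in zip(*np.nonzero(self.boundary))
        ]
        geom = unary_union(cells) if cells else None
        return {
            "type": "Feature",
            "properties": {"threshold": self.threshold},
            "geometry": mapping(geom) if geom is not None else None,
        }


# -- median trajectory -------------------------------------------------------


def _to_plane(tracks: list[np.ndarray]):
    """Project lon/lat tracks to a shared local planar km frame."""
    all_pts = np.vstack(tracks)
    lon0, lat0 = all_pts[:, 0].mean(), all_pts[:, 1].mean()
    cos0 = np.cos(np.radians(lat0))
    planar = [np.column_stack(((tr[:, 0] - lon0) * KM_PER_DEG * cos0,
                               (tr[:, 1] - lat0) * KM_PER_DEG)) for tr in tracks]
    return planar, (lon0, lat0, cos0)


def _from_plane(pts: np.ndarray, frame) -> np.ndarray:
    lon0, lat0, cos0 = frame
    return np.column_stack((pts[:, 0] / (KM_PER_DEG * cos0) + lon0,
                            pts[:, 1] / KM_PER_DEG + lat0))


def _segment_intersections(p0, p1, starts, ends):
    """Params (ua, ub) where segment p0->p1 crosses each of starts->ends."""
    d1 = p1 - p0
    d2 = ends - starts
    denom = d1[0] * d2[:, 1] - d1[1] * d2[:, 0]
    qp = starts - p0
    with np.errstate(divide="ignore", invalid="ignore"):
        ua = (qp[:, 0] * d2[:, 1] - qp[:, 1] * d2[:, 0]) / denom
        ub = (qp[:, 0] * d1[1] - qp[:, 1] * d1[0]) / denom
    valid = (np.abs(denom) > 1e-12) & (ua >= 0) & (ua <= 1) & (ub >= 0) & (ub <= 1)
    return ua, ub, valid


def median_trajectory(tracks: list[np.ndarray]) -> MedianTrajectory:
    """Median trajectory by intersection switching.

    Follow one track until it crosses another, switch to the crossed track
    at the intersection point, and repeat; the result is always composed of
    pieces of actual trajectories and is bounded by the outermost tracks.
    Starts from the track whose first point is nearest the centroid of all
    start points; at multi-way crossings the first intersection in
    arc-length order wins, ties broken by lowest track index.
    """
    tracks = [np.asarray(tr, dtype=float) for tr in tracks]
    if not tracks:
        raise ValueError("need at least one trajectory")
    if len(tracks) == 1:
        return MedianTrajectory(tracks[0].copy(),
                                [(0, (0, max(len(tracks[0]) - 2, 0)))])
    planar, frame = _to_plane(tracks)
    starts0 = np.array([tr[0] for tr in planar])
    centroid = starts0.mean(axis=0)
    cur = int(np.argmin(np.hypot(*(starts0 - centroid).T)))

    seg_starts = {a: tr[:-1] for a, tr in enumerate(planar)}
    seg_ends = {a: tr[1:] for a, tr in enumerate(planar)}
    others_cache: dict[int, tuple] = {}

    def others(a):
        if a not in others_cache:
            idx, st, en = [], [], []
            for b, tr in enumerate(planar):
                if b == a or len(tr) < 2:
                    continue
                nseg = len(tr) - 1
                idx.append(np.column_stack((np.full(nseg, b), np.arange(nseg))))
                st.append(seg_starts[b])
                en.append(seg_ends[b])
            if idx:
                others_cache[a] = (np.vstack(idx), np.vstack(st), np.vstack(en))
            else:
                others_cache[a] = (np.zeros((0, 2), int),
                                   np.zeros((0, 2)), np.zeros((0, 2)))
        return others_cache[a]

    eps = 1e-9
    max_switches = 4 * sum(max(len(tr) - 1, 0) for tr in planar)
    vertices = [planar[cur][0]]
    provenance: list[tuple[int, tuple[int, int]]] = []
    seg = 0
    u = 0.0
    span_start = seg
    switches = 0
    while True:
        if seg >= len(planar[cur]) - 1:
            provenance.append((cur, (span_start, max(seg - 1, span_start))))
            break
        p0, p1 = planar[cur][seg], planar[cur][seg + 1]
        hit = None
        if switches < max_switches:
            ids, st, en = others(cur)
            if len(st):
                ua, ub, valid = _segment_intersections(p0, p1, st, en)
                valid &= ua > u + eps
                if valid.any():
                    cand = np.flatnonzero(valid)
                    # first crossing along the walk; ties to the lowest track id
                    order = np.lexsort((ids[cand, 0], ua[cand]))
                    k = cand[order[0]]
                    hit = (float(ua[k]), int(ids[k, 0]), int(ids[k, 1]),
                           float(ub[k]))
        if hit is None:
            vertices.append(p1)
            seg += 1
            u = -eps
            continue
        ua_k, b, jb, vb = hit
        point = p0 + ua_k * (p1 - p0)
        vertices.append(point)
        provenance.append((cur, (span_start, seg)))
        cur, seg, u = b, jb, vb
        span_start = seg
        switches += 1
    verts = _from_plane(np.asarray(vertices), frame)
    return MedianTrajectory(verts, provenance)


# -- occupancy spread --------------------------------------------------------


def spread_region(tracks: list[np.ndarray], bin_size: float = 0.25,
                  threshold: float = 0.05) -> SpreadRegion:
    """Relative-frequency occupancy histogram and its above-threshold bins."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    pts = np.vstack([np.asarray(tr, dtype=float) for tr in tracks])
    lon_lo = np.floor(pts[:, 0].min() / bin_size) * bin_size
    lat_lo = np.floor(pts[:, 1].min() / bin_size) * bin_size
    n_lon = max(int(np.ceil((pts[:, 0].max() - lon_lo) / bin_size)), 1)
    n_lat = max(int(np.ceil((pts[:, 1].max() - lat_lo) / bin_size)), 1)
    lon_edges = lon_lo + bin_size * np.arange(n_lon + 1)
    lat_edges = lat_lo + bin_size * np.arange(n_lat + 1)
    hist, _, _ = np.histogram2d(pts[:, 1], pts[:, 0],
                                bins=(lat_edges, lon_edges))
    freq = hist / hist.sum()
    return SpreadRegion(lon_edges, lat_edges, freq, threshold, freq >= threshold)


# -- ensemble series ---------------------------------------------------------


def arrivals_over_time(ensemble: list[TrajectorySet],
                       config: ScenarioConfig | None = None) -> TimeSeries:
    """Cumulative arrivals: initial population minus agents still migrating."""
    times = ensemble[0].times
    per = np.stack([
        (ts.arrival_time[None, :] <= times[:, None]).sum(axis=1).astype(float)
        if ts.n_agents else np.zeros_like(times)
        for ts in ensemble
    ])
    return TimeSeries(times, per.mean(axis=0), per.std(axis=0, ddof=0), per)


def mean_distance_to_target(ensemble: list[TrajectorySet],
                            target: tuple[float, float]) -> TimeSeries:
    """Great-circle distance from the live-population centroid to the target."""
    times = ensemble[0].times
    per = np.zeros((len(ensemble), times.size))
    for r, ts in enumerate(ensemble):
        live = np.isnan(ts.arrival_time)[None, :] | \
            (ts.arrival_time[None, :] > times[:, None])
        last = np.nan
        for k in range(times.size):
            m = live[k]
            if m.any():
                lon_c = ts.lon[k, m].mean()
                lat_c = ts.lat[k, m].mean()
                last = float(haversine_km(lon_c, lat_c, target[0], target[1]))
            per[r, k] = last
    return TimeSeries(times, per.mean(axis=0), per.std(axis=0, ddof=0), per)


def mean_detected_whales(ensemble: list[TrajectorySet]) -> TimeSeries:
    """Daily mean of per-agent detectable-conspecific counts over live agents."""
    times = ensemble[0].times
    days = np.unique(np.floor(times / 24.0).astype(int))
    per = np.full((len(ensemble), days.size), np.nan)
    for r, ts in enumerate(ensemble):
        live = np.isnan(ts.arrival_time)[None, :] | \
            (ts.arrival_time[None, :] > times[:, None])
        for di, d in enumerate(days):
            in_day = (times >= 24.0 * d) & (times < 24.0 * (d + 1))
            counts = ts.n_detected[in_day]
            alive = live[in_day]
            if alive.any():
                per[r, di] = counts[alive].mean()
    mean = np.nanmean(per, axis=0)
    sd = np.nanstd(per, axis=0, ddof=0)
    return TimeSeries(days.astype(float) * 24.0, mean, sd, per)
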