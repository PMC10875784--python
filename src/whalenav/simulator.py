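"""Time-stepping engine for the collective-migration model.

Agents follow a velocity-jump random walk: fixed heading and speed between
exponentially-distributed reorientation events, plus passive advection by
ocean currents.  Heading selection at each reorientation combines inherent
target knowledge, detected conspecific headings, and noise/land avoidance
(see :mod:`whalenav.navigation`).  Moves that would land an agent on shore
or outside the gridded domain are aborted with an immediate reorientation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .acoustics import AcousticParams, received_level
from .environment import (
    DomainError,
    LandMask,
    Position,
    TimeGridField,
    bearing,
    deepest_water_direction,
    displace_many,
    haversine_km,
    noise_descent_direction,
)
from .navigation import (
    InfoLossParams,
    LandResponseParams,
    NavParams,
    NoiseResponseParams,
    fuse_headings,
    inherent_kappa,
    land_avoidance_weight,
    noise_avoidance_weight,
    resolve_behaviour,
    sample_inherent_heading,
    wrap_angle,
)

_WEIGHT_EPS = 1e-4  # below this an avoidance weight is treated as inactive


class ConfigError(ValueError):
    pass


class SimulationError(RuntimeError):
    pass


@dataclass
class EnvironmentBundle:
    """The four layers a simulation needs: noise, currents, depth, land."""

    noise: TimeGridField
    current: TimeGridField | None
    depth: TimeGridField
    land: LandMask

    def checksum(self) -> str:
        h = hashlib.sha256()
        for arr in (self.noise.values, self.depth.values, self.land.mask):
            h.update(np.ascontiguousarray(arr).tobytes())
        if self.current is not None:
            h.update(np.ascontiguousarray(self.current.values).tobytes())
        return h.hexdigest()[:16]


@dataclass
class WhaleState:
    """One agent: position, active heading, reorientation clock, arrival."""

    id: int
    position: Position
    heading: float
    next_reorientation: float
    arrived: bool = False
    arrival_time: float | None = None
    n_detected: int = 0


@dataclass
class ScenarioConfig:
    """Full parameterization of one simulation scenario."""

    n_whales: int = 100
    start_box: tuple[float, float, float, float] = (4.5, 5.5, 53.5, 54.5)  # W,E,S,N
    target: tuple[float, float] = (-5.0, 61.0)  # lon, lat
    arrival_radius_km: float = 50.0
    duration_h: float = 744.0
    dt_h: float = 0.1
    n_repeats: int = 10
    seed: int = 0
    detection_enabled: bool = True
    nav: NavParams = field(default_factory=NavParams)
    noise_response: NoiseResponseParams = field(default_factory=NoiseResponseParams)
    land_response: LandResponseParams = field(default_factory=LandResponseParams)
    info_loss: InfoLossParams = field(default_factory=InfoLossParams)
    acoustics: AcousticParams = field(default_factory=AcousticParams)
    environment: EnvironmentBundle | dict | None = None

    def __post_init__(self):
        if self.dt_h <= 0 or self.dt_h > 1.0:
            raise ConfigError("dt must lie in (0, 1] hours")
        if self.n_whales < 0 or self.n_repeats < 1:
            raise ConfigError("need n_whales >= 0 and n_repeats >= 1")
        self.info_loss.validate(self.nav.kappa_base)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            k: v for k, v in self.__dict__.items()
            if k not in ("nav", "noise_response", "land_response",
                         "info_loss", "acoustics", "environment")
        }
        d["start_box"] = list(self.start_box)
        d["target"] = list(self.target)
        d["nav"] = asdict(self.nav)
        d["noise_response"] = asdict(self.noise_response)
        d["land_response"] = asdict(self.land_response)
        d["info_loss"] = asdict(self.info_loss)
        d["acoustics"] = asdict(self.acoustics)
        if isinstance(self.environment, dict):
            d["environment"] = self.environment
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        kw = {
            "nav": NavParams(**d.pop("nav", {})),
            "noise_response": NoiseResponseParams(**d.pop("noise_response", {})),
            "land_response": LandResponseParams(**d.pop("land_response", {})),
            "info_loss": InfoLossParams(**d.pop("info_loss", {})),
            "acoustics": AcousticParams(**d.pop("acoustics", {})),
        }
        if "start_box" in d:
            d["start_box"] = tuple(d["start_box"])
        if "target" in d:
            d["target"] = tuple(d["target"])
        return cls(**d, **kw)

    def config_hash(self) -> str:
        d = self.to_dict()
        if isinstance(self.environment, EnvironmentBundle):
            d["environment"] = self.environment.checksum()
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def resolve_environment(self) -> EnvironmentBundle:
        if isinstance(self.environment, EnvironmentBundle):
            return self.environment
        if isinstance(self.environment, dict):
            from .scenarios import build_environment

            return build_environment(self.environment, duration_h=self.duration_h)
        raise ConfigError("scenario has no environment layers or recipe")


@dataclass
class TrajectorySet:
    """Ensemble-ready record of one simulation repeat.

    Arrays are indexed ``(time, agent)``; positions of arrived agents are
    frozen at their arrival location from arrival onward.
    """

    times: np.ndarray          # (nt,)
    lon: np.ndarray            # (nt, n)
    lat: np.ndarray
    heading: np.ndarray
    n_detected: np.ndarray
    arrival_time: np.ndarray   # (n,), nan = never arrived
    seed: int | None = None
    config_hash: str = ""

    @property
    def n_agents(self) -> int:
        return self.lon.shape[1]

    def arrived_by(self, t: float) -> np.ndarray:
        return ~np.isnan(self.arrival_time) & (self.arrival_time <= t)

    def to_dataframe(self, repeat: int = 0) -> pd.DataFrame:
        nt, n = self.lon.shape
        tt = np.repeat(self.times, n)
        ids = np.tile(np.arange(n), nt)
        arrived = self.arrival_time[ids]
        return pd.DataFrame({
            "repeat": repeat,
            "id": ids,
            "t_hours": tt,
            "lon": self.lon.ravel(),
            "lat": self.lat.ravel(),
            "heading_rad": self.heading.ravel(),
            "n_detected": self.n_detected.ravel().astype(int),
            "arrived": ~np.isnan(arrived) & (arrived <= tt),
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrajectorySet":
        times = np.unique(df["t_hours"].to_numpy(float))
        ids = np.unique(df["id"].to_numpy(int))
        nt, n = times.size, ids.size
        df = df.sort_values(["t_hours", "id"])
        shape = (nt, n)
        arrived = df["arrived"].to_numpy(bool).reshape(shape)
        tgrid = np.broadcast_to(times[:, None], shape)
        arrival = np.full(n, np.nan)
        for j in range(n):
            hit = np.flatnonzero(arrived[:, j])
            if hit.size:
                arrival[j] = tgrid[hit[0], j]
        return cls(
            times=times,
            lon=df["lon"].to_numpy(float).reshape(shape),
            lat=df["lat"].to_numpy(float).reshape(shape),
            heading=df["heading_rad"].to_numpy(float).reshape(shape),
            n_detected=df["n_detected"].to_numpy(float).reshape(shape),
            arrival_time=arrival,
        )


# -- core operations ---------------------------------------------------------


def initialize(config: ScenarioConfig, rng: np.random.Generator,
               env: EnvironmentBundle | None = None) -> list[WhaleState]:
    """Seed the population: uniform in the start box, heading to the target."""
    env = env or config.resolve_environment()
    w, e, s, n = config.start_box
    cell_lon = env.land.lon.coordinates
    cell_lat = env.land.lat.coordinates
    in_box = np.ix_((cell_lat >= s) & (cell_lat <= n), (cell_lon >= w) & (cell_lon <= e))
    if env.land.mask[in_box].any():
        raise ConfigError("start region overlaps land")
    target = Position(*config.target)
    pop: list[WhaleState] = []
    for i in range(config.n_whales):
        lon = rng.uniform(w, e)
        lat = rng.uniform(s, n)
        pos = Position(lon, lat)
        pop.append(WhaleState(
            id=i,
            position=pos,
            heading=bearing(pos, target),
            next_reorientation=rng.exponential(1.0 / config.nav.reorientation_rate),
        ))
    return pop


def detection_counts(population: Sequence[WhaleState], noise_at_agents: np.ndarray,
                     params: AcousticParams) -> np.ndarray:
    """Pairwise detection matrix: entry (i, j) True if i can detect j's call."""
    n = len(population)
    if n == 0:
        return np.zeros((0, 0), dtype=bool)
    lons = np.array([w.position.lon for w in population])
    lats = np.array([w.position.lat for w in population])
    r_km = haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
    rl = received_level(params.source_level, r_km * 1000.0, params.gamma)
    det = (rl - noise_at_agents[:, None] >= params.snr_min) & (rl >= params.rl_min)
    np.fill_diagonal(det, False)
    return det


def step(population: list[WhaleState], env: EnvironmentBundle,
         config: ScenarioConfig, t: float, dt: float,
         rng: np.random.Generator) -> list[WhaleState]:
    """Advance every live agent from ``t`` to ``t + dt`` in place."""
    live = [w for w in population if not w.arrived]
    if not live:
        return population
    lons = np.array([w.position.lon for w in live])
    lats = np.array([w.position.lat for w in live])
    try:
        noise_here = np.atleast_1d(env.noise.interp(lons, lats, t))
        depth_here = np.atleast_1d(env.depth.interp(lons, lats, t))
    except DomainError as err:
        raise SimulationError(f"agent left the environment domain at t={t}: {err}")

    if config.detection_enabled:
        det = detection_counts(live, noise_here, config.acoustics)
    else:
        det = np.zeros((len(live), len(live)), dtype=bool)
    headings_now = np.array([w.heading for w in live])
    for i, w in enumerate(live):
        w.n_detected = int(det[i].sum())

    target = Position(*config.target)
    for i, w in enumerate(live):
        if t < w.next_reorientation:
            continue
        kappa = inherent_kappa(float(noise_here[i]), config.nav, config.info_loss)
        own = sample_inherent_heading(bearing(w.position, target), kappa, rng)
        neighbour_headings = headings_now[det[i]]
        mu, kap = fuse_headings(own, neighbour_headings,
                                config.nav.alpha, config.nav.beta, rng)
        nav_heading = float(wrap_angle(rng.vonmises(mu, kap)))
        w_na = noise_avoidance_weight(float(noise_here[i]), config.noise_response)
        w_la = land_avoidance_weight(float(depth_here[i]), config.land_response)
        noise_dir = (noise_descent_direction(env.noise, w.position, t)
                     if w_na > _WEIGHT_EPS else None)
        land_dir = (deepest_water_direction(env.depth, w.position)
                    if w_la > _WEIGHT_EPS else None)
        w.heading = resolve_behaviour(nav_heading, noise_dir, land_dir,
                                      w_na, w_la, rng)
        w.next_reorientation = t + rng.exponential(
            1.0 / config.nav.reorientation_rate)

    # displacement: active swimming plus passive advection
    headings_new = np.array([w.heading for w in live])
    move_e = config.nav.speed_kmh * dt * np.cos(headings_new)
    move_n = config.nav.speed_kmh * dt * np.sin(headings_new)
    if env.current is not None:
        cur = np.atleast_2d(env.current.interp(lons, lats, t))
        move_e = move_e + cur[:, 0] * dt
        move_n = move_n + cur[:, 1] * dt
    dist = np.hypot(move_e, move_n)
    direction = np.arctan2(move_n, move_e)
    new_lon, new_lat = displace_many(lons, lats, direction, dist)

    w_box, e_box, s_box, n_box = env.noise.bbox
    blocked = (
        (new_lon < w_box) | (new_lon > e_box) | (new_lat < s_box) | (new_lat > n_box)
        | env.land.is_land(new_lon, new_lat)
    )
    dist_to_target = haversine_km(new_lon, new_lat, *config.target)
    for i, w in enumerate(live):
        if blocked[i]:
            # aborted landward/out-of-domain move: stay put, reorient next step
            w.next_reorientation = t
            continue
        w.position = Position(float(new_lon[i]), float(new_lat[i]))
        if dist_to_target[i] <= config.arrival_radius_km:
            w.arrived = True
            w.arrival_time = t + dt
    return population


def run(config: ScenarioConfig, seed=None,
        env: EnvironmentBundle | None = None) -> TrajectorySet:
    """One full simulation repeat, recorded at every time step."""
    env = env or config.resolve_environment()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pop = initialize(config, rng, env)
    n_steps = int(round(config.duration_h / config.dt_h))
    times = np.arange(n_steps + 1) * config.dt_h
    n = len(pop)
    lon = np.zeros((n_steps + 1, n))
    lat = np.zeros((n_steps + 1, n))
    heading = np.zeros((n_steps + 1, n))
    n_det = np.zeros((n_steps + 1, n))

    def snapshot_positions(k: int):
        for j, w in enumerate(pop):
            lon[k, j] = w.position.lon
            lat[k, j] = w.position.lat
            heading[k, j] = w.heading

    def snapshot_counts(k: int):
        # counts set by step() at time t_k; valid for agents live at t_k
        for j, w in enumerate(pop):
            n_det[k, j] = w.n_detected

    for k in range(n_steps):
        snapshot_positions(k)
        step(pop, env, config, float(times[k]), config.dt_h, rng)
        snapshot_counts(k)
    snapshot_positions(n_steps)
    # the final row needs a fresh detection pass at the end time
    live = [w for w in pop if not w.arrived]
    if live and config.detection_enabled:
        lons = np.array([w.position.lon for w in live])
        lats = np.array([w.position.lat for w in live])
        noise_here = np.atleast_1d(env.noise.interp(lons, lats, float(times[-1])))
        det = detection_counts(live, noise_here, config.acoustics)
        for i, w in enumerate(live):
            n_det[-1, w.id] = det[i].sum()

    arrival = np.array([np.nan if w.arrival_time is None else w.arrival_time
                        for w in pop])
    seed_val = config.seed if seed is None else seed
    return TrajectorySet(times, lon, lat, heading, n_det, arrival,
                         seed=seed_val if isinstance(seed_val, (int, np.integer)) else None,
                         config_hash=config.config_hash())


def run_ensemble(config: ScenarioConfig,
                 env: EnvironmentBundle | None = None) -> list[TrajectorySet]:
    """Independent repeats with seeds spawned from the scenario seed."""
    env = env or config.resolve_environment()
    children = np.random.SeedSequence(config.seed).spawn(config.n_repeats)
    out = []
    for child in children:
        ts = run(config, seed=child, env=env)
        ts.seed = int(child.entropy) if isinstance(child.entropy, int) else None
        out.append(ts)
    return out


def save_trajectories(runs: Sequence[TrajectorySet], path) -> None:
    pd.concat([ts.to_dataframe(repeat=r) for r, ts in enumerate(runs)],
              ignore_index=True).to_csv(path, index=False)


def load_trajectories(path) -> list[TrajectorySet]:
    df = pd.read_csv(path)
    return [TrajectorySet.from_dataframe(g)
            for _, g in df.groupby("repeat", sort=True)]
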