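"""Per-reorientation heading selection.

An agent's new heading blends three ingredients:

1. an *inherent* heading sampled from a von Mises distribution centred on
   the target bearing, whose concentration may erode with ambient noise;
2. *collective* information — the headings of detectable conspecifics,
   fused with the agent's own sample through weighted resultant vectors;
3. *behavioural overrides* — sigmoidal noise-avoidance and land-avoidance
   weights that steer motion down the noise gradient or toward deep water.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .acoustics import AcousticParams, is_detectable
from .environment import TimeGridField, haversine_km, wrap_angle

KAPPA_MAX = 500.0  # cap: the Bessel ratio saturates and sampling overflows beyond


@dataclass(frozen=True)
class NavParams:
    kappa_base: float = 1.0   # inherent concentration toward the target
    alpha: float = 0.5        # own-vs-group weight for the mean direction
    beta: float = 0.5         # own-vs-group weight for the concentration
    speed_kmh: float = 6.0
    reorientation_rate: float = 1.0  # mean reorientations per hour

    def __post_init__(self):
        if self.kappa_base < 0:
            raise ValueError("kappa_base must be >= 0")
        if not (0 <= self.alpha <= 1 and 0 <= self.beta <= 1):
            raise ValueError("alpha and beta must lie in [0, 1]")
        if self.speed_kmh < 0 or self.reorientation_rate <= 0:
            raise ValueError("speed must be >= 0 and reorientation rate positive")


@dataclass(frozen=True)
class NoiseResponseParams:
    """Noise-avoidance sigmoid: equals 0.5 exactly at the threshold level."""

    threshold_db: float = 120.0
    transition_db: float = 5.0  # N_s; scale of the regular-to-avoidance transition

    def __post_init__(self):
        if self.transition_db <= 0:
            raise ValueError("transition scale must be positive")


@dataclass(frozen=True)
class LandResponseParams:
    """Land-avoidance sigmoid: equals 0.5 exactly at the threshold depth."""

    threshold_m: float = 30.0
    slope_per_m: float = 0.5

    def __post_init__(self):
        if self.threshold_m <= 0:
            raise ValueError("threshold depth must be positive")


@dataclass(frozen=True)
class InfoLossParams:
    """Noise-dependent erosion of inherent navigation information.

    ``threshold_db`` is the noise level at which half of the losable
    information is gone.  ``enabled=False`` keeps the concentration at its
    baseline regardless of noise.
    """

    enabled: bool = False
    kappa_min: float = 0.0
    threshold_db: float = 110.0  # N_IL
    slope_per_db: float = 0.1

    def validate(self, kappa_base: float) -> None:
        if not 0 <= self.kappa_min <= kappa_base:
            raise ValueError("kappa_min must lie in [0, kappa_base]")


# -- concentration / circular statistics -------------------------------------


def inherent_kappa(noise_db: float, nav: NavParams, loss: InfoLossParams) -> float:
    """Inherent concentration at ambient noise ``noise_db``; decreasing in noise."""
    if not loss.enabled:
        return nav.kappa_base
    s = 0.5 - 0.5 * np.tanh(loss.slope_per_db * (noise_db - loss.threshold_db))
    return float(loss.kappa_min + (nav.kappa_base - loss.kappa_min) * s)


def sample_inherent_heading(target_bearing: float, kappa: float,
                            rng: np.random.Generator) -> float:
    """One von Mises draw centred on the target bearing."""
    if kappa < 0:
        raise ValueError("concentration must be >= 0")
    return float(wrap_angle(rng.vonmises(target_bearing, kappa)))


def _bessel_ratio(kappa: float) -> float:
    """A(kappa) = I1(kappa) / I0(kappa), the mean resultant length."""
    return i1e(kappa) / i0e(kappa)


def resultant_to_concentration(rbar: float) -> float:
    """Invert the Bessel ratio: the kappa whose mean resultant length is rbar."""
    if not 0.0 <= rbar <= 1.0:
        raise ValueError("mean resultant length must lie in [0, 1]")
    if rbar == 0.0:
        return 0.0
    if rbar >= 1.0 - 1e-9 or rbar >= _bessel_ratio(KAPPA_MAX):
        return KAPPA_MAX
    return float(brentq(lambda k: _bessel_ratio(k) - rbar, 1e-12, KAPPA_MAX,
                        xtol=1e-12, rtol=1e-14))


def fuse_headings(own: float, neighbours, alpha: float, beta: float,
                  rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Fuse own heading with observed neighbour headings.

    The location estimate is the direction of the weighted resultant
    ``alpha * u(own) + (1 - alpha) * mean(u(neighbour))``.  The concentration
    estimate pools the information of the n + 1 sources: it is the length of
    the *summed* weighted resultant, ``(n + 1) * |beta * u(own) +
    (1 - beta) * mean(u(neighbour))|``, capped at :data:`KAPPA_MAX`.  Pooling
    (rather than inverting the mean resultant length) is what makes agreeing
    sources reinforce each other, so certainty grows with group size — the
    many-wrongs benefit; a moment inversion of the normalized resultant makes
    the collective term exactly cancel at equilibrium.

    With no neighbours the agent keeps its own heading at the concentration
    cap (the solitary limit).  A zero resultant yields kappa 0 and a
    uniformly random direction.
    """
    if not (0 <= alpha <= 1 and 0 <= beta <= 1):
        raise ValueError("alpha and beta must lie in [0, 1]")
    neighbours = np.asarray(neighbours, dtype=float)
    if neighbours.size == 0:
        return float(wrap_angle(own)), KAPPA_MAX
    n = neighbours.size
    group = np.array([np.mean(np.cos(neighbours)), np.mean(np.sin(neighbours))])
    u_own = np.array([np.cos(own), np.sin(own)])
    r_loc = alpha * u_own + (1 - alpha) * group
    r_conc = beta * u_own + (1 - beta) * group
    kappa = min((n + 1) * float(np.hypot(*r_conc)), KAPPA_MAX)
    if np.hypot(*r_loc) < 1e-12:
        rng = rng or np.random.default_rng()
        mu = float(rng.uniform(-np.pi, np.pi))
    else:
        mu = float(np.arctan2(r_loc[1], r_loc[0]))
    return mu, kappa


# -- detection ---------------------------------------------------------------


def detectable_neighbours(agent, others, noise: TimeGridField, t: float,
                          params: AcousticParams) -> list[float]:
    """Headings of every other agent whose call is detectable by ``agent``.

    The ambient noise is evaluated at the receiver's position; observed
    headings are the senders' current active headings, taken as error-free.
    """
    others = [o for o in others if o is not agent]
    if not others:
        return []
    n_here = float(noise.interp(agent.position.lon, agent.position.lat, t))
    lons = np.array([o.position.lon for o in others])
    lats = np.array([o.position.lat for o in others])
    r_m = haversine_km(agent.position.lon, agent.position.lat, lons, lats) * 1000.0
    ok = is_detectable(params.source_level, r_m, n_here, params)
    return [float(o.heading) for o, good in zip(others, np.atleast_1d(ok)) if good]


# -- behavioural weighting ---------------------------------------------------


def noise_avoidance_weight(noise_db, p: NoiseResponseParams):
    """Fraction of motion devoted to fleeing noise; 0.5 at the threshold."""
    out = 0.5 + 0.5 * np.tanh((np.asarray(noise_db, dtype=float)
                               - p.threshold_db) / p.transition_db)
    return float(out) if out.ndim == 0 else out


def land_avoidance_weight(depth_m, p: LandResponseParams):
    """Fraction of motion devoted to seeking deep water; 0.5 at the threshold."""
    out = 0.5 - 0.5 * np.tanh(p.slope_per_m *
                              (np.asarray(depth_m, dtype=float) - p.threshold_m))
    return float(out) if out.ndim == 0 else out


def resolve_behaviour(nav_heading: float, noise_dir: float | None,
                      land_dir: float | None, w_na: float, w_la: float,
                      rng: np.random.Generator | None = None) -> float:
    """Blend navigation, noise-avoidance and land-avoidance directions.

    If the avoidance weights sum above one they are rescaled proportionally;
    the remainder goes to navigation.  An avoidance direction that is
    undefined (flat gradient) hands its weight back to navigation.  A zero
    resultant is tie-broken uniformly at random.
    """
    if not (0 <= w_na <= 1 and 0 <= w_la <= 1):
        raise ValueError("weights must lie in [0, 1]")
    total = w_na + w_la
    if total > 1.0:
        w_na, w_la = w_na / total, w_la / total
    if noise_dir is None:
        w_na = 0.0
    if land_dir is None:
        w_la = 0.0
    w_nav = 1.0 - w_na - w_la
    vx = w_nav * np.cos(nav_heading) + w_na * np.cos(noise_dir or 0.0) \
        + w_la * np.cos(land_dir or 0.0)
    vy = w_nav * np.sin(nav_heading) + w_na * np.sin(noise_dir or 0.0) \
        + w_la * np.sin(land_dir or 0.0)
    if np.hypot(vx, vy) < 1e-12:
        rng = rng or np.random.default_rng()
        return float(rng.uniform(-np.pi, np.pi))
    return float(np.arctan2(vy, vx))
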