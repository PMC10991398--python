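"""Agent-based battle-royale match simulator with planted ground truth.

One match: ``n_teams`` teams of ``team_size`` players parachute onto a
square map, with landing anchors drawn from a hotspot mixture (risk-seeking
teams) or uniformly (risk-averse teams).  Team centroids then perform a
random walk constrained to a play circle that shrinks on the game's
schedule (5-minute initial hold, 22.8 m/s contraction, 3 min 20 s pauses at
trigger diameters, 30-minute cap); members scatter around their centroid
with a per-team cohesion sigma.  Every 10-second interval each alive team
is eliminated with probability

    logistic( alpha + alpha_slope * t / T - eta ),
    eta = b_high * s_high + b_med * s_med + b_low * s_low
        + q_high * exp(-m_exp * z) * s_high**2
        + b_collab_low * (collab_low - 9) + b_collab_high * (collab_high - 8)
        + b_risk * risk_frac

where the s_* are the team's running interdependence-state shares, collab_*
the running normalized pair-distance extremes, risk_frac the running
fraction of member-time in high-risk cells, and z the team's standardized
experience.  ``eta`` is a *performance* (survival) score, so a negative
quadratic coefficient ``q_high`` plants an interior performance optimum in
the high-interdependence share — the inverted U.  Experience moderates the
curvature multiplicatively: ``exp(-m_exp * z)`` attenuates ``q_high``
toward zero as experience grows (without ever reversing its sign), so the
inverted U flattens to a near-linear effect for experienced teams.  Final ranks are the reverse
elimination order (rank 1 = last team alive; cap survivors are ranked by
final hazard, simultaneous eliminations broken by team id).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import behavior as bhv
from .risk import CELL_CM, RiskHeatmap, build_heatmap, risk_cell_threshold
from .telemetry import (
    MAP_SIDE_CM,
    SAMPLE_INTERVAL_S,
    LandingEvent,
    MatchMeta,
    MatchTelemetry,
    PlayerProfile,
    PlayerState,
)

# Experience mixture emulating the cohort's three experience strata:
# (mean, sd, weight); means are the printed stratum centers, weights the
# stratum share of the team population.
EXPERIENCE_MIXTURE = (
    (0.013, 0.15, 0.607),
    (3.358, 0.50, 0.218),
    (4.914, 0.80, 0.175),
)


def _mixture_moments(mixture) -> tuple[float, float]:
    mu = sum(w * m for m, _, w in mixture)
    ex2 = sum(w * (s**2 + m**2) for m, s, w in mixture)
    return mu, math.sqrt(ex2 - mu**2)


@dataclass(frozen=True)
class HazardParams:
    """Coefficients of the planted per-interval survival score (see module
    docstring).  ``alpha`` is the baseline elimination log-odds at match
    start, rising by ``alpha_slope`` over the match (the shrinking circle
    concentrates elimination pressure at the end-game); all other
    coefficients act on the performance side (positive = protective)."""

    alpha: float = -4.0
    alpha_slope: float = 0.0
    b_high: float = 3.0
    b_med: float = 0.3
    b_low: float = -1.0
    q_high: float = -4.0
    m_exp: float = 1.5
    b_collab_low: float = 0.25
    b_collab_high: float = 0.15
    b_risk: float = -0.8

    # Centering constants for the (large, slowly varying) collab features.
    collab_low_center: float = 9.0
    collab_high_center: float = 8.0


def null_hazard(**overrides) -> HazardParams:
    """Hazard with no planted curvature or moderation (q_high = m_exp = 0)."""
    return replace(HazardParams(), q_high=0.0, m_exp=0.0, **overrides)


@dataclass(frozen=True)
class ShrinkSchedule:
    """Play-circle schedule: initial hold, constant-rate contraction, fixed
    pauses at trigger diameters, hard duration cap."""

    hold0_s: float = 300.0
    shrink_rate_cm_per_s: float = 2280.0
    pause_s: float = 200.0
    cap_s: float = 1800.0
    trigger_diameters: tuple[float, ...] | None = None  # None: geometric halving

    def triggers_for(self, map_side_cm: float) -> tuple[float, ...]:
        if self.trigger_diameters is not None:
            return tuple(self.trigger_diameters)
        d0 = map_side_cm * math.sqrt(2.0)
        return (d0 / 2, d0 / 4, d0 / 8, d0 / 16)

    def breakpoints(self, map_side_cm: float):
        """(times, radii) knots of the piecewise-linear radius function."""
        r0 = map_side_cm * math.sqrt(2.0) / 2.0
        ts, rs = [0.0, self.hold0_s], [r0, r0]
        t, r = self.hold0_s, r0
        for d in self.triggers_for(map_side_cm):
            rt = d / 2.0
            if rt >= r:
                continue
            t += (r - rt) / self.shrink_rate_cm_per_s
            ts.append(t)
            rs.append(rt)
            r = rt
            t += self.pause_s
            ts.append(t)
            rs.append(r)
        if r > 0:
            t += r / self.shrink_rate_cm_per_s
            ts.append(t)
            rs.append(0.0)
        ts.append(max(self.cap_s, t) + 1.0)
        rs.append(rs[-1])
        return np.array(ts), np.array(rs)


def shrink_radius(t_s, schedule: ShrinkSchedule, map_side_cm: float):
    """Play-circle radius (cm) at time(s) ``t_s``; constant after the cap."""
    t = np.minimum(np.asarray(t_s, dtype=float), schedule.cap_s)
    if np.any(t < 0):
        raise ValueError("t_s must be non-negative")
    ts, rs = schedule.breakpoints(map_side_cm)
    out = np.interp(t, ts, rs)
    return float(out) if out.ndim == 0 else out


def default_hotspots(map_name: str) -> tuple[tuple[float, float, float], ...]:
    """Five landing hotspots at fixed relative positions, weight-decreasing."""
    side = MAP_SIDE_CM[map_name]
    rel = [
        (0.30, 0.30, 0.30),
        (0.70, 0.62, 0.25),
        (0.52, 0.18, 0.20),
        (0.18, 0.72, 0.15),
        (0.82, 0.85, 0.10),
    ]
    return tuple((fx * side, fy * side, w) for fx, fy, w in rel)


@dataclass
class SimulationConfig:
    """All knobs of the generator, with the study's defaults.

    Per-team parameters (``landing_risk_preference``, ``cohesion_sigma_cm``,
    ``experience_mean``) accept a scalar (constant across teams), a length-
    ``n_teams`` array (fixed per team), or a ``(low, high)`` pair sampled
    per team per match — uniformly, except cohesion which is sampled
    log-uniformly so interdependence shares spread over their full range.
    """

    seed: int = 0
    map_name: str = "Erangel"
    n_teams: int = 25
    team_size: int = 4
    n_matches: int = 1
    schedule: ShrinkSchedule = field(default_factory=ShrinkSchedule)
    hotspot_centers: tuple[tuple[float, float, float], ...] | None = None
    hotspot_sigma_cm: float = 6000.0
    landing_risk_preference: object = (0.0, 1.0)
    cohesion_sigma_cm: object = (1500.0, 60000.0)
    step_sigma_cm: float = 6000.0
    experience_mean: object = None  # None: draw from experience_mixture
    experience_sd: float = 0.1
    # Log-normal spread of per-member dispersion around the team's cohesion
    # sigma: individual members roam more or less than their team (flankers,
    # anchors), so pair-distance extremes decouple from co-clustering.
    member_sigma_spread: float = 1.2
    experience_mixture: tuple = EXPERIENCE_MIXTURE
    hazard: HazardParams = field(default_factory=HazardParams)
    outlier_rate: float = 0.0
    n_reference_landings: int = 20000

    def __post_init__(self):
        if self.map_name not in MAP_SIDE_CM:
            raise ValueError(f"unknown map {self.map_name!r}")
        if self.n_teams < 1 or self.team_size < 1 or self.n_matches < 1:
            raise ValueError("n_teams, team_size, n_matches must be >= 1")
        if self.hotspot_centers is None:
            self.hotspot_centers = default_hotspots(self.map_name)
        w = np.array([h[2] for h in self.hotspot_centers], dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("hotspot weights must be non-negative and normalizable")

    @property
    def map_side_cm(self) -> int:
        return MAP_SIDE_CM[self.map_name]


def _per_team(spec, n: int, rng: np.random.Generator, log: bool = False) -> np.ndarray:
    """Resolve a per-team parameter spec (scalar / array / range pair)."""
    if np.isscalar(spec):
        return np.full(n, float(spec))
    arr = np.asarray(spec, dtype=float)
    if arr.shape == (2,) and arr.size != n:
        lo, hi = arr
        if log:
            return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        return rng.uniform(lo, hi, size=n)
    if arr.shape == (n,):
        return arr.copy()
    raise ValueError(f"per-team parameter spec {spec!r} not scalar, pair or length-{n}")


# ---------------------------------------------------------------------------
# Match generation stages
# ---------------------------------------------------------------------------

def simulate_landings(
    config: SimulationConfig,
    rng: np.random.Generator,
    risk_pref: np.ndarray | None = None,
    cohesion: np.ndarray | None = None,
):
    """Draw team landing anchors and member landing positions for one match.

    Returns ``(anchors, positions)`` with shapes (n_teams, 2) and
    (n_teams, team_size, 2); coordinates are clipped to the map.
    """
    n, m, side = config.n_teams, config.team_size, config.map_side_cm
    if risk_pref is None:
        risk_pref = _per_team(config.landing_risk_preference, n, rng)
    if cohesion is None:
        cohesion = _per_team(config.cohesion_sigma_cm, n, rng, log=True)

    centers = np.array([(h[0], h[1]) for h in config.hotspot_centers])
    weights = np.array([h[2] for h in config.hotspot_centers], dtype=float)
    weights = weights / weights.sum()

    on_hotspot = rng.random(n) < risk_pref
    anchors = rng.uniform(0, side, size=(n, 2))
    k_hot = int(on_hotspot.sum())
    if k_hot and len(centers):
        idx = rng.choice(len(centers), size=k_hot, p=weights)
        anchors[on_hotspot] = centers[idx] + rng.normal(
            0.0, config.hotspot_sigma_cm, size=(k_hot, 2)
        )
    anchors = np.clip(anchors, 0, side)
    positions = anchors[:, None, :] + rng.normal(0.0, 1.0, size=(n, m, 2)) * cohesion[
        :, None, None
    ]
    return anchors, np.clip(positions, 0, side)


def simulate_trajectories(
    config: SimulationConfig,
    anchors: np.ndarray,
    cohesion: np.ndarray,
    rng: np.random.Generator,
):
    """Team-centroid random walks inside the shrinking circle.

    Centroids take Gaussian steps (``step_sigma_cm`` per 10 s), are
    projected back inside the current circle (centered on the map) and
    clipped to the map; members are centroid + Gaussian offsets with the
    team's cohesion sigma, radially truncated at 3 sigma so every position
    stays within circle radius + 3 sigma.  Returns positions of shape
    (T, n_teams, team_size, 2) on the 10-second grid.
    """
    side = config.map_side_cm
    sched = config.schedule
    times = np.arange(0.0, sched.cap_s + SAMPLE_INTERVAL_S / 2, SAMPLE_INTERVAL_S)
    radii = shrink_radius(times, sched, side)
    T, n, m = len(times), config.n_teams, config.team_size
    center = np.array([side / 2.0, side / 2.0])

    centroids = np.empty((T, n, 2))
    c = anchors.astype(float).copy()
    for k in range(T):
        if k > 0:
            c = c + rng.normal(0.0, config.step_sigma_cm, size=(n, 2))
        off = c - center
        dist = np.hypot(off[:, 0], off[:, 1])
        r = radii[k]
        outside = dist > r
        if outside.any():
            scale = np.where(dist > 0, np.minimum(1.0, r / np.maximum(dist, 1e-9)), 0.0)
            c = np.where(outside[:, None], center + off * scale[:, None], c)
        c = np.clip(c, 0, side)
        centroids[k] = c

    offsets = rng.normal(0.0, 1.0, size=(T, n, m, 2))
    norm = np.hypot(offsets[..., 0], offsets[..., 1])
    clip = np.minimum(1.0, 3.0 / np.maximum(norm, 1e-12))
    offsets *= clip[..., None]
    member_sigma = cohesion[:, None] * np.exp(
        config.member_sigma_spread * rng.normal(size=(n, m))
    )
    positions = centroids[:, :, None, :] + offsets * member_sigma[None, :, :, None]
    return times, np.clip(positions, 0, side)


def _behavior_arrays(positions: np.ndarray, times: np.ndarray, duration_s: float,
                     eps_cm: float = bhv.DEFAULT_EPS_CM):
    """Per-timepoint interdependence state and collab extremes for all teams.

    Returns dict of (T, n_teams) arrays: ``high``/``med``/``low`` state
    indicators and ``cmax``/``cmin`` normalized pair-distance extremes.
    """
    T, n, m, _ = positions.shape
    diff = positions[:, :, :, None, :] - positions[:, :, None, :, :]
    dist = np.sqrt((diff**2).sum(axis=4))  # (T, n, m, m)
    adj = (dist <= eps_cm).reshape(T * n, m, m)
    alive = np.ones((T * n, m), dtype=bool)
    ncomp = bhv._component_counts(adj, alive).reshape(T, n)

    iu, ju = np.triu_indices(m, k=1)
    pair = dist[:, :, iu, ju]  # (T, n, P)
    frac = np.maximum(bhv.NORM_FLOOR, (duration_s - times) / duration_s)
    nd = np.log1p(pair / frac[:, None, None])
    return {
        "high": (ncomp == 1).astype(float),
        "low": (ncomp == m).astype(float),
        "med": ((ncomp > 1) & (ncomp < m)).astype(float),
        "cmax": nd.max(axis=2),
        "cmin": nd.min(axis=2),
    }


def _prefix_mean(x: np.ndarray) -> np.ndarray:
    """Running mean along axis 0."""
    k = np.arange(1, x.shape[0] + 1, dtype=float)
    return np.cumsum(x, axis=0) / k[:, None]


def simulate_eliminations(
    config: SimulationConfig,
    running: dict[str, np.ndarray],
    z_exp: np.ndarray,
    rng: np.random.Generator,
):
    """Draw the team elimination process from the planted hazard.

    ``running`` holds (T, n_teams) prefix-mean feature arrays (keys
    ``high``, ``med``, ``low``, ``cmax``, ``cmin``, ``risk``); ``z_exp`` the
    standardized team experience.  Returns ``(final_ranks, elim_idx,
    end_idx)`` where ``elim_idx[i]`` is the timepoint index at which team i
    died (-1 for survivors) and ``end_idx`` the index at which the match
    ended (one team left, or the cap).
    """
    hp = config.hazard
    T, n = running["high"].shape
    eta = (
        hp.b_high * running["high"]
        + hp.b_med * running["med"]
        + hp.b_low * running["low"]
        + hp.q_high * np.exp(-hp.m_exp * z_exp[None, :]) * running["high"] ** 2
        + hp.b_collab_low * (running["cmax"] - hp.collab_low_center)
        + hp.b_collab_high * (running["cmin"] - hp.collab_high_center)
        + hp.b_risk * running["risk"]
    )
    t_frac = np.arange(T, dtype=float)[:, None] / max(T - 1, 1)
    logodds = hp.alpha + hp.alpha_slope * t_frac - eta
    p_elim = 1.0 / (1.0 + np.exp(-logodds))

    alive = np.ones(n, dtype=bool)
    elim_idx = np.full(n, -1, dtype=int)
    u = rng.random((T, n))
    end_idx = T - 1
    for k in range(1, T):
        killed = alive & (u[k] < p_elim[k])
        elim_idx[killed] = k
        alive &= ~killed
        if alive.sum() <= 1:
            end_idx = k
            break

    final_hazard = p_elim[end_idx]
    order = sorted(
        range(n),
        key=lambda i: (0, final_hazard[i], i) if alive[i] else (1, -elim_idx[i], i),
    )
    final_ranks = np.empty(n, dtype=int)
    for rank, i in enumerate(order, start=1):
        final_ranks[i] = rank
    return final_ranks, elim_idx, end_idx


# ---------------------------------------------------------------------------
# Whole matches and cohorts
# ---------------------------------------------------------------------------

def simulate_proportional_odds(
    X: np.ndarray, beta: np.ndarray, thresholds: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw ordinal outcomes from an exact cumulative-logit model.

    ``P(y <= j | x) = logistic(theta_j - x.beta)``; returns levels
    ``1..len(thresholds)+1``.  This is the calibration oracle for the
    ordinal estimators: any effect not in ``X.beta`` is exactly absent.
    """
    X = np.asarray(X, dtype=float)
    xb = X @ np.asarray(beta, dtype=float)
    latent = xb + rng.logistic(size=len(X))
    theta = np.asarray(thresholds, dtype=float)
    return 1 + np.searchsorted(theta, latent)


@dataclass
class CohortResult:
    """Simulated matches plus planted ground truth and the reference
    landing heatmap (held-out cohort) used by the hazard."""

    matches: list[MatchTelemetry]
    ground_truth: pd.DataFrame
    reference_heatmap: RiskHeatmap
    reference_cutoff: float


def simulate_reference_heatmap(config: SimulationConfig, rng: np.random.Generator) -> RiskHeatmap:
    """Landing heatmap from a held-out sample of individual players drawn
    from the same landing law (mean risk preference of the cohort)."""
    n_ref = config.n_reference_landings
    side = config.map_side_cm
    pref = np.mean(_per_team(config.landing_risk_preference, 1024, rng))
    centers = np.array([(h[0], h[1]) for h in config.hotspot_centers])
    weights = np.array([h[2] for h in config.hotspot_centers], dtype=float)
    weights /= weights.sum()
    xy = rng.uniform(0, side, size=(n_ref, 2))
    on_hot = rng.random(n_ref) < pref
    k = int(on_hot.sum())
    if k and len(centers):
        idx = rng.choice(len(centers), size=k, p=weights)
        xy[on_hot] = centers[idx] + rng.normal(0, config.hotspot_sigma_cm, size=(k, 2))
    return build_heatmap(np.clip(xy, 0, side), config.map_name)


def simulate_match(
    config: SimulationConfig,
    match_id: str,
    rng: np.random.Generator,
    reference_heatmap: RiskHeatmap,
    reference_cutoff: float,
):
    """Simulate one full match; returns (MatchTelemetry, ground-truth rows)."""
    n, m, side = config.n_teams, config.team_size, config.map_side_cm
    team_ids = [f"{match_id}-t{i:02d}" for i in range(n)]

    risk_pref = _per_team(config.landing_risk_preference, n, rng)
    cohesion = _per_team(config.cohesion_sigma_cm, n, rng, log=True)
    if config.experience_mean is None:
        mix = config.experience_mixture
        comp = rng.choice(len(mix), size=n, p=[w for _, _, w in mix])
        mus = np.array([mix[c][0] for c in comp])
        sds = np.array([mix[c][1] for c in comp])
        exp_mean = np.maximum(0.0, mus + sds * rng.normal(size=n))
    else:
        exp_mean = _per_team(config.experience_mean, n, rng)
    rank_points = np.maximum(
        0.0, exp_mean[:, None] + config.experience_sd * rng.normal(size=(n, m))
    )
    team_exp = rank_points.mean(axis=1)
    mix_mu, mix_sd = _mixture_moments(config.experience_mixture)
    z_exp = (team_exp - mix_mu) / mix_sd

    anchors, land_pos = simulate_landings(config, rng, risk_pref, cohesion)
    times, positions = simulate_trajectories(config, anchors, cohesion, rng)
    T = len(times)

    # Hacker/bot-style coordinate spikes, for exercising the Z-filter.
    outlier = np.zeros(n, dtype=bool)
    if config.outlier_rate > 0:
        outlier = rng.random(n) < config.outlier_rate
        corners = np.where((np.arange(T) % 2)[:, None], side * 0.999, side * 0.001)
        for i in np.where(outlier)[0]:
            # hacker-style teleporting between opposite corners every step,
            # so the anomaly is extreme wherever the team happens to be
            positions[1:, i, 0, :] = corners[1:]

    feats = _behavior_arrays(positions, times, config.schedule.cap_s)
    ncells = reference_heatmap.n_cells_per_side
    ii = np.minimum(
        (positions[..., 0] / reference_heatmap.cell_cm).astype(int), ncells - 1
    )
    jj = np.minimum(
        (positions[..., 1] / reference_heatmap.cell_cm).astype(int), ncells - 1
    )
    in_high = reference_heatmap.counts[ii, jj] > reference_cutoff  # (T, n, m)
    running = {key: _prefix_mean(feats[key]) for key in ("high", "med", "low", "cmax", "cmin")}
    running["risk"] = _prefix_mean(in_high.mean(axis=2))

    final_ranks, elim_idx, end_idx = simulate_eliminations(config, running, z_exp, rng)

    states: list[PlayerState] = []
    for i, tid in enumerate(team_ids):
        last = elim_idx[i] if elim_idx[i] >= 0 else end_idx
        for k in range(last + 1):
            t = times[k]
            dead_now = elim_idx[i] == k
            for j in range(m):
                states.append(
                    PlayerState(
                        player_id=f"{tid}-p{j}",
                        team_id=tid,
                        t_s=float(t),
                        x_cm=float(positions[k, i, j, 0]),
                        y_cm=float(positions[k, i, j, 1]),
                        alive=not dead_now,
                    )
                )

    landings = [
        LandingEvent(
            player_id=f"{tid}-p{j}",
            team_id=tid,
            x_cm=float(land_pos[i, j, 0]),
            y_cm=float(land_pos[i, j, 1]),
            t_s=0.0,
        )
        for i, tid in enumerate(team_ids)
        for j in range(m)
    ]
    profiles = [
        PlayerProfile(player_id=f"{tid}-p{j}", rank_points=float(rank_points[i, j]))
        for i, tid in enumerate(team_ids)
        for j in range(m)
    ]
    meta = MatchMeta(
        match_id=match_id,
        map_name=config.map_name,
        map_side_cm=side,
        n_players=n * m,
        team_size=m,
        duration_s=float(times[end_idx]) if end_idx > 0 else SAMPLE_INTERVAL_S,
    )
    match = MatchTelemetry(
        meta=meta,
        states=states,
        landings=landings,
        profiles=profiles,
        final_ranks={tid: int(final_ranks[i]) for i, tid in enumerate(team_ids)},
    )

    hp = config.hazard
    gt = pd.DataFrame(
        {
            "match_id": match_id,
            "team_id": team_ids,
            "cohesion_sigma_cm": cohesion,
            "landing_risk_preference": risk_pref,
            "experience_mean": team_exp,
            "z_exp": z_exp,
            "q_eff": hp.q_high * np.exp(-hp.m_exp * z_exp),
            "share_high_full": running["high"][-1],
            "share_high_at_end": running["high"][
                np.where(elim_idx >= 0, elim_idx, end_idx), np.arange(n)
            ],
            "outlier": outlier,
            "final_rank": final_ranks,
            "elim_t_s": np.where(elim_idx >= 0, elim_idx * SAMPLE_INTERVAL_S, np.nan),
        }
    )
    return match, gt


def simulate_cohort(config: SimulationConfig) -> CohortResult:
    """Simulate ``config.n_matches`` matches under one seed.

    Seeds fan out through a ``SeedSequence`` (one child per match, plus one
    for the reference heatmap), so any prefix of the cohort is reproducible
    independently of the rest.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_matches + 1)
    ref_rng = np.random.default_rng(children[0])
    heatmap = simulate_reference_heatmap(config, ref_rng)
    cutoff = risk_cell_threshold(heatmap)

    matches, gts = [], []
    for idx in range(config.n_matches):
        rng = np.random.default_rng(children[idx + 1])
        match_id = f"m{config.seed:08x}-{idx:04d}"
        match, gt = simulate_match(config, match_id, rng, heatmap, cutoff)
        matches.append(match)
        gts.append(gt)
    return CohortResult(
        matches=matches,
        ground_truth=pd.concat(gts, ignore_index=True),
        reference_heatmap=heatmap,
        reference_cutoff=cutoff,
    )
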