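"""Shared fixtures: small simulated cohorts and hand-built matches."""

import numpy as np
import pandas as pd
import pytest

from squadperf.simulate import ShrinkSchedule, SimulationConfig, simulate_cohort
from squadperf.telemetry import (
    LandingEvent,
    MatchMeta,
    MatchTelemetry,
    PlayerProfile,
    PlayerState,
)


def small_config(seed=0, **overrides) -> SimulationConfig:
    """A fast config: 8 teams of 4 on Karakin, 10-minute cap."""
    defaults = dict(
        seed=seed,
        map_name="Karakin",
        n_teams=8,
        team_size=4,
        n_matches=2,
        schedule=ShrinkSchedule(cap_s=600.0),
        n_reference_landings=4000,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config(seed=11, n_matches=3))


@pytest.fixture
def tiny_match() -> MatchTelemetry:
    """Hand-built 2-team, 2-player-per-team match on Karakin."""
    meta = MatchMeta(
        match_id="tiny", map_name="Karakin", map_side_cm=204_000,
        n_players=4, team_size=2, duration_s=30.0,
    )
    states = [
        PlayerState(f"p{i}", f"t{i // 2}", t, 1000.0 * (i + 1), 2000.0 * (i + 1))
        for t in (0.0, 10.0, 20.0)
        for i in range(4)
    ]
    landings = [
        LandingEvent(f"p{i}", f"t{i // 2}", 500.0 * (i + 1), 700.0 * (i + 1))
        for i in range(4)
    ]
    profiles = [PlayerProfile(f"p{i}", float(i)) for i in range(4)]
    return MatchTelemetry(
        meta=meta, states=states, landings=landings, profiles=profiles,
        final_ranks={"t0": 1, "t1": 2},
    )


def team_table(positions_by_time, duration_cols=True) -> pd.DataFrame:
    """Build a one-team location table from {t: [(x, y), ...]}."""
    rows = []
    for t, pts in positions_by_time.items():
        for j, (x, y) in enumerate(pts):
            rows.append(
                {
                    "player_id": f"p{j}",
                    "team_id": "t0",
                    "t_s": float(t),
                    "x_cm": float(x),
                    "y_cm": float(y),
                    "alive": True,
                }
            )
    return pd.DataFrame(rows)


def brute_force_components(points, eps) -> np.ndarray:
    """Union-find connected components of the epsilon graph (oracle)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(pts[i] - pts[j])) <= eps:
                parent[find(i)] = find(j)
    roots = {}
    labels = np.empty(n, dtype=int)
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        labels[i] = roots[r]
    return labels
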