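"""Behavioral-interdependence and collaboration features from player locations.

At every sampled timepoint the alive members of a team are clustered with
DBSCAN at minPts = 1 and epsilon = 100 m (which is exactly the connected
components of the graph joining members within epsilon).  A timepoint is in
state HIGH when all alive members form one cluster, LOW when every member is
a singleton, MEDIUM otherwise.  States are aggregated to time shares, and
within-team pair distances (log-transformed and normalized by remaining
match time to undo the shrinking play area) are aggregated to the
"loose collaboration" (farthest pair) and "tight collaboration" (closest
pair) features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

#: DBSCAN epsilon: 100 m in centimeters.
DEFAULT_EPS_CM = 10_000.0

#: Floor on the remaining-time fraction used in distance normalization.
NORM_FLOOR = 0.1

HIGH, MEDIUM, LOW = "HIGH", "MEDIUM", "LOW"


@dataclass
class TeamBehaviorFeatures:
    """Per team-match behavior features.

    Shares are fractions of *evaluated* timepoints (those with >= 2 alive
    members) spent in each interdependence state; ``collab_low`` /
    ``collab_high`` are time-averages of the per-timepoint farthest /
    closest normalized log pair distance.  ``sd_dist`` is the standard
    deviation of all normalized pair distances (pooled over evaluated
    timepoints); it feeds the match-level dispersion control.
    """

    share_high: float
    share_med: float
    share_low: float
    collab_high: float
    collab_low: float
    n_timepoints: int
    sd_dist: float = float("nan")

    @property
    def valid(self) -> bool:
        return self.n_timepoints > 0


def team_centroid(points) -> np.ndarray:
    """Arithmetic mean of 2-D points; the team's Euclidean centroid."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("team_centroid requires at least one point")
    return pts.reshape(-1, 2).mean(axis=0)


def centroid_distances(points) -> np.ndarray:
    """Euclidean distance of every point to the team centroid."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.size == 0:
        raise ValueError("centroid_distances requires at least one point")
    c = pts.mean(axis=0)
    return np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])


def cluster_players(points, eps_cm: float = DEFAULT_EPS_CM, min_pts: int = 1) -> np.ndarray:
    """DBSCAN cluster labels for a set of 2-D player positions.

    With ``min_pts = 1`` (the default used throughout) no point can be
    noise and the clustering equals the connected components of the graph
    joining points at Euclidean distance <= ``eps_cm``; that case is
    computed directly as graph components.  Larger ``min_pts`` falls back
    to scikit-learn's DBSCAN (noise labelled -1).

    Labels are renumbered in order of first occurrence, so they are
    deterministic and independent of the backend.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n == 0:
        raise ValueError("cluster_players requires at least one point")
    if eps_cm <= 0:
        raise ValueError("eps_cm must be positive")
    if min_pts == 1:
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        adj = d2 <= eps_cm**2
        _, labels = connected_components(csr_matrix(adj), directed=False)
    else:
        from sklearn.cluster import DBSCAN

        labels = DBSCAN(eps=eps_cm, min_samples=min_pts).fit(pts).labels_
    return _canonical_labels(labels)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    out = np.empty(len(labels), dtype=int)
    mapping: dict[int, int] = {}
    nxt = 0
    for i, lab in enumerate(labels):
        lab = int(lab)
        if lab == -1:  # DBSCAN noise stays -1
            out[i] = -1
            continue
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[lab]
    return out


def classify_interdependence(labels, n_alive: int) -> str:
    """Map cluster labels of alive members to HIGH / MEDIUM / LOW."""
    if n_alive < 2:
        raise ValueError("interdependence undefined for fewer than 2 alive members")
    n_clusters = len(set(int(l) for l in labels))
    if n_clusters == 1:
        return HIGH
    if n_clusters == n_alive:
        return LOW
    return MEDIUM


def pair_distances(points) -> np.ndarray:
    """All C(n, 2) unordered pairwise Euclidean distances."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise ValueError("pair_distances requires at least two points")
    idx = np.array(list(itertools.combinations(range(len(pts)), 2)))
    diff = pts[idx[:, 0]] - pts[idx[:, 1]]
    return np.hypot(diff[:, 0], diff[:, 1])


def normalize_distance(d_cm, t_s, duration_s: float, floor: float = NORM_FLOOR):
    """Remaining-time-normalized log distance.

    ``log1p(d / max(floor, (duration - t) / duration))``: late-match
    distances are up-weighted to offset the shrinking play area, and the
    log1p keeps coincident players (d = 0) finite at 0.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    frac = np.maximum(floor, (duration_s - np.asarray(t_s, dtype=float)) / duration_s)
    out = np.log1p(d / frac)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Vectorized per-team feature extraction
# ---------------------------------------------------------------------------

def _positions_cube(team_table: pd.DataFrame):
    """Pivot one team's location table to (T, m, 2) with NaN where absent/dead.

    Only rows with ``alive == True`` contribute (the final record at death
    time is excluded from team features).
    """
    tab = team_table[team_table["alive"].astype(bool)]
    times = np.sort(tab["t_s"].unique())
    players = np.sort(tab["player_id"].unique())
    t_idx = {t: i for i, t in enumerate(times)}
    p_idx = {p: j for j, p in enumerate(players)}
    cube = np.full((len(times), len(players), 2), np.nan)
    ti = tab["t_s"].map(t_idx).to_numpy()
    pj = tab["player_id"].map(p_idx).to_numpy()
    cube[ti, pj, 0] = tab["x_cm"].to_numpy(dtype=float)
    cube[ti, pj, 1] = tab["y_cm"].to_numpy(dtype=float)
    return cube, times


def _component_counts(adj: np.ndarray, alive: np.ndarray) -> np.ndarray:
    """Number of connected components among alive nodes, per timepoint.

    ``adj``: (T, m, m) boolean epsilon-adjacency (False on dead rows/cols);
    ``alive``: (T, m) boolean.  Uses boolean matrix powers (m is the team
    size, <= a handful, so reachability closes in m - 1 multiplications).
    """
    T, m, _ = adj.shape
    eye = np.eye(m, dtype=bool)
    reach = adj | (eye[None, :, :] & alive[:, :, None] & alive[:, None, :])
    a = reach.astype(np.float32)
    for _ in range(max(m - 2, 0)):
        a = np.matmul(a, a)
        np.clip(a, 0.0, 1.0, out=a)
    reach = a > 0.5
    # Encode each row's reachability set as a bitmask; components = number of
    # distinct bitmasks among alive rows.  Dead rows get unique sentinels so
    # they inflate the unique count by exactly the number of dead rows.
    weights = (1 << np.arange(m)).astype(np.int64)
    codes = (reach * weights[None, None, :]).sum(axis=2)
    sentinel = (1 << m) + np.arange(m, dtype=np.int64)
    codes = np.where(alive, codes, sentinel[None, :])
    codes_sorted = np.sort(codes, axis=1)
    uniq = 1 + (np.diff(codes_sorted, axis=1) != 0).sum(axis=1)
    n_dead = (~alive).sum(axis=1)
    return uniq - n_dead


def collaboration_features(
    team_table: pd.DataFrame,
    duration_s: float,
    eps_cm: float = DEFAULT_EPS_CM,
    floor: float = NORM_FLOOR,
) -> TeamBehaviorFeatures:
    """Compute :class:`TeamBehaviorFeatures` for one team-match.

    ``team_table`` is the slice of :func:`squadperf.telemetry.location_table`
    for one (match, team).  Timepoints with fewer than two alive members are
    excluded; if none remain the result has ``n_timepoints == 0`` and NaN
    features (flagged invalid downstream).
    """
    cube, times = _positions_cube(team_table)
    T, m, _ = cube.shape
    if T == 0 or m < 2:
        return TeamBehaviorFeatures(*(float("nan"),) * 5, 0)

    alive = ~np.isnan(cube[:, :, 0])
    n_alive = alive.sum(axis=1)
    evaluated = n_alive >= 2

    diff = cube[:, :, None, :] - cube[:, None, :, :]
    dist = np.sqrt((diff**2).sum(axis=3))  # (T, m, m), NaN where a member is dead
    with np.errstate(invalid="ignore"):
        adj = dist <= eps_cm
    adj &= alive[:, :, None] & alive[:, None, :]

    ncomp = _component_counts(adj, alive)

    iu, ju = np.triu_indices(m, k=1)
    pair_d = dist[:, iu, ju]  # (T, P) with NaN for pairs involving dead members
    frac = np.maximum(floor, (duration_s - times) / duration_s)
    norm_d = np.log1p(pair_d / frac[:, None])

    if not evaluated.any():
        return TeamBehaviorFeatures(*(float("nan"),) * 5, 0)

    ncomp_e = ncomp[evaluated]
    n_alive_e = n_alive[evaluated]
    n_eval = int(evaluated.sum())
    share_high = float((ncomp_e == 1).mean())
    share_low = float((ncomp_e == n_alive_e).mean())
    # A timepoint with n_alive == 2 and 2 clusters is LOW, not MEDIUM.
    share_med = 1.0 - share_high - share_low

    nd_e = norm_d[evaluated]
    with np.errstate(invalid="ignore"):
        per_t_max = np.nanmax(nd_e, axis=1)
        per_t_min = np.nanmin(nd_e, axis=1)
    collab_low = float(per_t_max.mean())
    collab_high = float(per_t_min.mean())
    pooled = nd_e[~np.isnan(nd_e)]
    sd_dist = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0

    return TeamBehaviorFeatures(
        share_high=share_high,
        share_med=share_med,
        share_low=share_low,
        collab_high=collab_high,
        collab_low=collab_low,
        n_timepoints=n_eval,
        sd_dist=sd_dist,
    )


BEHAVIOR_CSV_COLUMNS = [
    "match_id",
    "team_id",
    "share_high",
    "share_med",
    "share_low",
    "collab_high",
    "collab_low",
    "n_timepoints",
]


def behavior_table(
    match_tables: dict[str, pd.DataFrame] | pd.DataFrame,
    durations: dict[str, float] | float,
    eps_cm: float = DEFAULT_EPS_CM,
) -> pd.DataFrame:
    """Behavior features for every team in one or many matches.

    ``match_tables`` is either a single location table with a ``match_id``
    column, or a mapping match_id -> location table; ``durations`` gives the
    match duration(s) in seconds.  Invalid team-matches (no timepoint with
    >= 2 alive members) are excluded.
    """
    if isinstance(match_tables, pd.DataFrame):
        groups = dict(tuple(match_tables.groupby("match_id")))
    else:
        groups = dict(match_tables)
    rows = []
    for match_id, table in groups.items():
        dur = durations if np.isscalar(durations) else durations[match_id]
        for team_id, team_tab in table.groupby("team_id"):
            f = collaboration_features(team_tab, duration_s=float(dur), eps_cm=eps_cm)
            if not f.valid:
                continue
            rows.append(
                {
                    "match_id": match_id,
                    "team_id": team_id,
                    "share_high": f.share_high,
                    "share_med": f.share_med,
                    "share_low": f.share_low,
                    "collab_high": f.collab_high,
                    "collab_low": f.collab_low,
                    "n_timepoints": f.n_timepoints,
                    "sd_dist": f.sd_dist,
                }
            )
    return pd.DataFrame(
        rows, columns=BEHAVIOR_CSV_COLUMNS + ["sd_dist"]
    )


def write_behavior_csv(table: pd.DataFrame, path) -> None:
    """Write the behavior feature CSV with exactly the documented columns."""
    table[BEHAVIOR_CSV_COLUMNS].to_csv(path, index=False)
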