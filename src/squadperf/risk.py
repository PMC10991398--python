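"""Landing-count heatmaps and team risk-taking features.

Each map is divided into 10 x 10 m cells (1000 cm); the number of reference
parachute landings in a cell is the riskiness of that cell (crowded landing
spots are resource-rich and contested).  A team's landing risk is the
max/min cell count over its members' landings; overtime risk accumulates
the time members spend in high-risk cells, where "high-risk" means a cell
count above the median of nonzero cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .telemetry import MAP_SIDE_CM, SAMPLE_INTERVAL_S, LandingEvent

#: Heatmap cell side: 10 m in centimeters.
CELL_CM = 1000


@dataclass
class RiskHeatmap:
    """Grid of landing counts at 10 m resolution for one map."""

    map_name: str
    cell_cm: int = CELL_CM
    counts: np.ndarray = field(default=None)  # (n_cells, n_cells) int

    def __post_init__(self):
        if self.map_name not in MAP_SIDE_CM:
            raise ValueError(f"unknown map {self.map_name!r}")
        n = self.n_cells_per_side
        if self.counts is None:
            self.counts = np.zeros((n, n), dtype=np.int64)
        else:
            self.counts = np.asarray(self.counts, dtype=np.int64)
            if self.counts.shape != (n, n):
                raise ValueError(
                    f"counts shape {self.counts.shape} != ({n}, {n}) for {self.map_name}"
                )

    @property
    def n_cells_per_side(self) -> int:
        return MAP_SIDE_CM[self.map_name] // self.cell_cm

    @property
    def n_landings(self) -> int:
        return int(self.counts.sum())


@dataclass
class RiskFeatures:
    """Per team-match risk features (see module docstring)."""

    landing_risk_high: int
    landing_risk_low: int
    time_high_risk_s: float
    time_low_risk_s: float
    risk_category: int = 0


def cell_index(x_cm, y_cm, cell_cm: int = CELL_CM, n_cells: int | None = None):
    """0-based half-open cell indices ``(floor(x/cell), floor(y/cell))``.

    The max-coordinate edge of the map belongs to the last cell.  Scalar or
    array inputs; out-of-bounds coordinates raise.
    """
    x = np.asarray(x_cm, dtype=float)
    y = np.asarray(y_cm, dtype=float)
    if n_cells is None:
        raise ValueError("n_cells is required")
    side = cell_cm * n_cells
    if np.any(x < 0) or np.any(y < 0) or np.any(x > side) or np.any(y > side):
        raise ValueError(f"coordinates out of [0, {side}]")
    i = np.minimum(np.floor(x / cell_cm).astype(int), n_cells - 1)
    j = np.minimum(np.floor(y / cell_cm).astype(int), n_cells - 1)
    if i.ndim == 0:
        return int(i), int(j)
    return i, j


def build_heatmap(landings, map_name: str, cell_cm: int = CELL_CM) -> RiskHeatmap:
    """Count landings per cell.  ``landings`` is a sequence of
    :class:`LandingEvent` or an (n, 2) array of coordinates."""
    hm = RiskHeatmap(map_name=map_name, cell_cm=cell_cm)
    if len(landings) == 0:
        return hm
    if isinstance(landings[0], LandingEvent):
        xy = np.array([(ev.x_cm, ev.y_cm) for ev in landings], dtype=float)
    else:
        xy = np.asarray(landings, dtype=float).reshape(-1, 2)
    n = hm.n_cells_per_side
    i, j = cell_index(xy[:, 0], xy[:, 1], cell_cm, n)
    np.add.at(hm.counts, (i, j), 1)
    return hm


def landing_risk(landing, heatmap: RiskHeatmap) -> int:
    """Cell count of a landing's cell in a reference heatmap."""
    if isinstance(landing, LandingEvent):
        x, y = landing.x_cm, landing.y_cm
    else:
        x, y = landing
    i, j = cell_index(x, y, heatmap.cell_cm, heatmap.n_cells_per_side)
    return int(heatmap.counts[i, j])


def team_landing_risk(member_risks) -> tuple[int, int]:
    """(max, min) landing-cell count over team members."""
    r = np.asarray(member_risks)
    if r.size == 0:
        raise ValueError("team_landing_risk requires at least one member")
    return int(r.max()), int(r.min())


def risk_cell_threshold(heatmap: RiskHeatmap) -> float:
    """Median count over nonzero cells; a cell is high-risk iff count > cutoff."""
    nz = heatmap.counts[heatmap.counts > 0]
    if nz.size == 0:
        raise ValueError("all-zero heatmap has no risk threshold")
    return float(np.median(nz))


def overtime_risk(
    team_table: pd.DataFrame,
    heatmap: RiskHeatmap,
    cutoff: float,
    interval_s: float = SAMPLE_INTERVAL_S,
) -> tuple[float, float]:
    """Time (s) in high-risk cells by the most risk-taking member and in
    low-risk cells by the least risk-taking member.

    Each sampled point while alive contributes ``interval_s`` seconds.  Both
    components take the max over members: the high-risk time of the member
    who most seeks risk, and the low-risk time of the member who most
    avoids it.
    """
    tab = team_table[team_table["alive"].astype(bool)]
    if len(tab) == 0:
        return 0.0, 0.0
    n = heatmap.n_cells_per_side
    i, j = cell_index(
        tab["x_cm"].to_numpy(float), tab["y_cm"].to_numpy(float), heatmap.cell_cm, n
    )
    high = heatmap.counts[i, j] > cutoff
    per_member = pd.DataFrame(
        {"player_id": tab["player_id"].to_numpy(), "high": high}
    ).groupby("player_id")["high"]
    t_high = per_member.sum() * interval_s
    t_low = (per_member.count() - per_member.sum()) * interval_s
    return float(t_high.max()), float(t_low.max())


def risk_category(values, q_low: float = 0.5, q_high: float = 0.5) -> np.ndarray:
    """Quantile-threshold labels in {-1, 0, +1} for a cohort of teams.

    -1 below ``quantile(q_low)``, +1 above ``quantile(q_high)``, 0 in
    between.  At the defaults (both 0.5, the cohort median) the 0 class only
    holds exact median ties.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("risk_category requires a cohort of >= 2 teams")
    lo = np.quantile(v, q_low)
    hi = np.quantile(v, q_high)
    out = np.zeros(v.shape, dtype=int)
    out[v < lo] = -1
    out[v > hi] = 1
    return out


RISK_CSV_COLUMNS = [
    "match_id",
    "team_id",
    "landing_risk_high",
    "landing_risk_low",
    "time_high_risk_s",
    "time_low_risk_s",
    "risk_category",
]


def risk_table(
    matches,
    heatmap: RiskHeatmap,
    location_tables: dict[str, pd.DataFrame],
    q_low: float = 0.5,
    q_high: float = 0.5,
) -> pd.DataFrame:
    """Risk features for every team of every match against a reference heatmap.

    ``matches`` is an iterable of :class:`squadperf.telemetry.MatchTelemetry`
    (for landings); ``location_tables`` maps match_id to its location table.
    Risk categories are assigned cohort-wide from ``time_high_risk_s``.
    """
    cutoff = risk_cell_threshold(heatmap)
    rows = []
    for match in matches:
        if match.meta.map_name != heatmap.map_name:
            raise ValueError(
                f"match {match.meta.match_id} on {match.meta.map_name}, "
                f"heatmap for {heatmap.map_name}"
            )
        by_team: dict[str, list[int]] = {}
        for ev in match.landings:
            by_team.setdefault(ev.team_id, []).append(landing_risk(ev, heatmap))
        table = location_tables[match.meta.match_id]
        for team_id, team_tab in table.groupby("team_id"):
            risks = by_team.get(team_id, [])
            if not risks:
                continue
            hi, lo = team_landing_risk(risks)
            t_hi, t_lo = overtime_risk(team_tab, heatmap, cutoff)
            rows.append(
                {
                    "match_id": match.meta.match_id,
                    "team_id": team_id,
                    "landing_risk_high": hi,
                    "landing_risk_low": lo,
                    "time_high_risk_s": t_hi,
                    "time_low_risk_s": t_lo,
                }
            )
    df = pd.DataFrame(rows, columns=RISK_CSV_COLUMNS[:-1])
    if len(df) >= 2:
        df["risk_category"] = risk_category(df["time_high_risk_s"], q_low, q_high)
    else:
        df["risk_category"] = 0
    return df


# ---------------------------------------------------------------------------
# Heatmap serialization: CSV triplets + metadata sidecar
# ---------------------------------------------------------------------------

def write_heatmap(heatmap: RiskHeatmap, csv_path, meta_path=None) -> None:
    """Write nonzero cells as (i, j, count) CSV plus a JSON metadata sidecar."""
    i, j = np.nonzero(heatmap.counts)
    pd.DataFrame({"i": i, "j": j, "count": heatmap.counts[i, j]}).to_csv(
        csv_path, index=False
    )
    meta_path = meta_path or str(csv_path) + ".meta.json"
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "map_name": heatmap.map_name,
                "cell_cm": heatmap.cell_cm,
                "n_cells_per_side": heatmap.n_cells_per_side,
                "n_landings": heatmap.n_landings,
            },
            fh,
        )


def read_heatmap(csv_path, meta_path=None) -> RiskHeatmap:
    meta_path = meta_path or str(csv_path) + ".meta.json"
    with open(meta_path, "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    hm = RiskHeatmap(map_name=meta["map_name"], cell_cm=meta["cell_cm"])
    trip = pd.read_csv(csv_path)
    hm.counts[trip["i"].to_numpy(int), trip["j"].to_numpy(int)] = trip[
        "count"
    ].to_numpy(int)
    return hm
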