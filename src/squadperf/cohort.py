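"""Team-match cohort assembly, outlier filtering, controls and strata.

One row per team per match: final rank, behavior and risk features, mean
member experience, match-level controls.  Outliers (hackers, bots, bugs)
are removed by a single-pass Z-score filter at 3 SD; teams are stratified
into LOW / MEDIUM / HIGH experience groups by 1-D K-means (k = 3) for the
simple-slopes (stratified) analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

STRATA = ("LOW", "MEDIUM", "HIGH")

#: Features filtered by default; matches the regression feature set.
DEFAULT_FILTER_VARS = [
    "share_high",
    "share_med",
    "share_low",
    "collab_high",
    "collab_low",
    "landing_risk_high",
    "landing_risk_low",
    "time_high_risk_s",
    "time_low_risk_s",
]


class JoinError(ValueError):
    """Keys failed to align when assembling team-match records."""


def assemble_records(
    behavior: pd.DataFrame,
    risk: pd.DataFrame,
    ranks: pd.DataFrame,
    profiles: pd.DataFrame,
) -> pd.DataFrame:
    """Inner-join features and ranks into one row per (match_id, team_id).

    ``ranks`` needs columns (match_id, team_id, final_rank); ``profiles``
    needs (match_id, team_id, player_id, rank_points) — team experience is
    the mean of member rank points.  A key present in one feature table but
    not another raises :class:`JoinError` naming the orphans.
    """
    keys = ["match_id", "team_id"]
    b_keys = set(map(tuple, behavior[keys].itertuples(index=False)))
    r_keys = set(map(tuple, risk[keys].itertuples(index=False)))
    only_b = sorted(b_keys - r_keys)
    only_r = sorted(r_keys - b_keys)
    if only_b or only_r:
        raise JoinError(
            f"behavior/risk key mismatch; behavior-only={only_b[:5]}, "
            f"risk-only={only_r[:5]}"
        )

    team_exp = (
        profiles.groupby(keys)["rank_points"].mean().rename("team_experience")
    )
    df = behavior.merge(risk, on=keys, validate="one_to_one")
    df = df.merge(ranks[keys + ["final_rank"]], on=keys, how="left")
    if df["final_rank"].isna().any():
        orphans = df.loc[df["final_rank"].isna(), keys].values.tolist()
        raise JoinError(f"teams without a final rank: {orphans[:5]}")
    df = df.merge(team_exp, on=keys, how="left")
    if df["team_experience"].isna().any():
        orphans = df.loc[df["team_experience"].isna(), keys].values.tolist()
        raise JoinError(f"teams without player profiles: {orphans[:5]}")
    df["final_rank"] = df["final_rank"].astype(int)
    return df


def zscore_filter(
    table: pd.DataFrame, variables, z_max: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass Z-score outlier filter.

    A row is dropped iff |x - mean| > z_max * sd for ANY listed variable,
    with mean/sd computed once on the input table (no re-estimation after
    drops).  Returns (kept, report); the report lists (row index, variable,
    z) for every offending value.  Zero-variance variables are skipped with
    a warning.
    """
    if len(table) < 2:
        raise ValueError("zscore_filter needs at least 2 rows")
    drop_mask = np.zeros(len(table), dtype=bool)
    report_rows = []
    for var in variables:
        x = table[var].to_numpy(dtype=float)
        mu, sd = np.nanmean(x), np.nanstd(x, ddof=0)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"zscore_filter: variable {var!r} has zero variance; skipped")
            continue
        z = (x - mu) / sd
        bad = np.abs(z) > z_max
        for pos in np.where(bad)[0]:
            report_rows.append(
                {"row": table.index[pos], "variable": var, "z": float(z[pos])}
            )
        drop_mask |= bad
    kept = table.loc[~drop_mask].copy()
    report = pd.DataFrame(report_rows, columns=["row", "variable", "z"])
    return kept, report


def conjoint_experience(rosters: pd.DataFrame) -> dict[str, float]:
    """Percentages of players with cross-match conjoint teammate experience.

    ``rosters``: columns (match_id, team_id, player_id).  A player has
    dyadic conjoint experience if some teammate recurs with them across two
    matches, triadic if two teammates recur together, quartet if three;
    ``overall_pct`` is any conjoint experience.  All values are percentages
    of distinct players.
    """
    teammates: dict[str, list[frozenset]] = {}
    for (_, _), group in rosters.groupby(["match_id", "team_id"]):
        members = frozenset(group["player_id"])
        for p in members:
            teammates.setdefault(p, []).append(members - {p})

    n_players = len(teammates)
    counts = {"overall": 0, "dyad": 0, "triad": 0, "quartet": 0}
    for p, mate_sets in teammates.items():
        best = 0
        for a in range(len(mate_sets)):
            for b in range(a + 1, len(mate_sets)):
                best = max(best, len(mate_sets[a] & mate_sets[b]))
        if best >= 1:
            counts["overall"] += 1
            counts["dyad"] += 1
        if best >= 2:
            counts["triad"] += 1
        if best >= 3:
            counts["quartet"] += 1
    scale = 100.0 / n_players if n_players else 0.0
    return {f"{k}_pct": v * scale for k, v in counts.items()}


def match_controls(records: pd.DataFrame, strategy_mix: bool = False) -> pd.DataFrame:
    """Match-level control columns, broadcast back to team rows.

    Per match: mean over teams of collab_low / collab_high, mean of each
    team's SD of pair distances (``sd_dist``), mean overtime risk, and
    optionally the mix of risk strategies (exploration / ambidexterity /
    exploitation shares from :func:`strategy_proxy`).
    """
    df = records.copy()
    g = df.groupby("match_id")
    df["mean_max_dist"] = g["collab_low"].transform("mean")
    df["mean_min_dist"] = g["collab_high"].transform("mean")
    if "sd_dist" in df.columns:
        df["mean_sd_dist"] = g["sd_dist"].transform("mean")
    df["match_mean_risk"] = g["time_high_risk_s"].transform("mean")
    if strategy_mix:
        evaluated = df["n_timepoints"].to_numpy(float) * 10.0
        labels = [
            strategy_proxy(t, e)
            for t, e in zip(df["time_high_risk_s"].to_numpy(float), evaluated)
        ]
        df["_strategy"] = labels
        for lab in ("exploration", "ambidexterity", "exploitation"):
            df[f"strategy_{lab}"] = df.groupby("match_id")["_strategy"].transform(
                lambda s, lab=lab: (s == lab).mean()
            )
        df = df.drop(columns=["_strategy"])
    return df


def strategy_proxy(time_high_risk_s: float, evaluated_time_s: float) -> str:
    """Documented proxy for the risk-strategy label: the fraction of
    evaluated time spent in high-risk cells, cut at 1/3 and 2/3."""
    if evaluated_time_s <= 0:
        raise ValueError("evaluated_time_s must be positive")
    r = time_high_risk_s / evaluated_time_s
    if r < 1 / 3:
        return "exploration"
    if r > 2 / 3:
        return "exploitation"
    return "ambidexterity"


@dataclass
class StratumAssignment:
    """K-means experience strata: centers sorted ascending and mapped to
    LOW / MEDIUM / HIGH."""

    centers: np.ndarray
    labels: np.ndarray  # array of strings from STRATA
    seed: int

    @property
    def sizes(self) -> dict[str, int]:
        return {s: int((self.labels == s).sum()) for s in STRATA}


def experience_strata(values, k: int = 3, seed: int = 0, n_init: int = 10) -> StratumAssignment:
    """1-D K-means stratification of team experience into k ordered groups."""
    v = np.asarray(values, dtype=float).reshape(-1, 1)
    if len(np.unique(v)) < k:
        raise ValueError(f"need >= {k} distinct experience values")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(v)
    order = np.argsort(km.cluster_centers_.ravel())
    if k != len(STRATA):
        names = [f"S{j}" for j in range(k)]
    else:
        names = list(STRATA)
    relabel = {int(order[j]): names[j] for j in range(k)}
    labels = np.array([relabel[int(c)] for c in km.labels_])
    return StratumAssignment(
        centers=np.sort(km.cluster_centers_.ravel()), labels=labels, seed=seed
    )


def prepare_cohort(
    behavior: pd.DataFrame,
    risk: pd.DataFrame,
    ranks: pd.DataFrame,
    profiles: pd.DataFrame,
    z_max: float = 3.0,
    filter_vars=None,
    k_strata: int = 3,
    seed: int = 0,
    strategy_mix: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Full prep stage: assemble, Z-filter, controls, strata.

    Returns (cohort table, report dict with drops / conjoint percentages /
    stratum centers and sizes / seed).
    """
    records = assemble_records(behavior, risk, ranks, profiles)
    filter_vars = [
        v for v in (filter_vars or DEFAULT_FILTER_VARS) if v in records.columns
    ]
    kept, dropped = zscore_filter(records, filter_vars, z_max=z_max)
    kept = match_controls(kept, strategy_mix=strategy_mix)

    conj = conjoint_experience(profiles[["match_id", "team_id", "player_id"]])
    strata = experience_strata(kept["team_experience"], k=k_strata, seed=seed)
    kept = kept.copy()
    kept["stratum"] = strata.labels
    # Standardized experience for interaction terms.
    mu, sd = kept["team_experience"].mean(), kept["team_experience"].std(ddof=0)
    kept["z_experience"] = (kept["team_experience"] - mu) / (sd if sd > 0 else 1.0)

    report = {
        "n_input": int(len(records)),
        "n_kept": int(len(kept)),
        "n_dropped": int(len(records) - len(kept)),
        "dropped": dropped.to_dict(orient="records"),
        "filter": {"z_max": z_max, "variables": filter_vars, "single_pass": True},
        "conjoint_experience": conj,
        "stratum_centers": strata.centers.tolist(),
        "stratum_sizes": strata.sizes,
        "seed": seed,
    }
    return kept, report
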