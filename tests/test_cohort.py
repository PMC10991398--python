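"""Cohort assembly, Z-filter, conjoint experience, controls, strata."""

import numpy as np
import pandas as pd
import pytest

from squadperf.cohort import (
    JoinError,
    assemble_records,
    conjoint_experience,
    experience_strata,
    match_controls,
    prepare_cohort,
    strategy_proxy,
    zscore_filter,
)
from squadperf.pipeline import compute_features, profiles_table, ranks_table
from squadperf.simulate import simulate_cohort

from conftest import small_config

rng = np.random.default_rng(2024)


def _toy_inputs(n_matches=3, n_teams=5):
    keys = [
        (f"m{i}", f"m{i}-t{j}") for i in range(n_matches) for j in range(n_teams)
    ]
    behavior = pd.DataFrame(
        {
            "match_id": [k[0] for k in keys],
            "team_id": [k[1] for k in keys],
            "share_high": rng.uniform(size=len(keys)),
            "share_med": 0.0,
            "share_low": 0.0,
            "collab_high": rng.uniform(5, 8, len(keys)),
            "collab_low": rng.uniform(8, 11, len(keys)),
            "n_timepoints": 50,
            "sd_dist": rng.uniform(0.5, 1.5, len(keys)),
        }
    )
    risk = pd.DataFrame(
        {
            "match_id": [k[0] for k in keys],
            "team_id": [k[1] for k in keys],
            "landing_risk_high": rng.integers(0, 20, len(keys)),
            "landing_risk_low": rng.integers(0, 5, len(keys)),
            "time_high_risk_s": rng.uniform(0, 600, len(keys)),
            "time_low_risk_s": rng.uniform(0, 600, len(keys)),
            "risk_category": 0,
        }
    )
    ranks = pd.DataFrame(
        {
            "match_id": [k[0] for k in keys],
            "team_id": [k[1] for k in keys],
            "final_rank": list(range(1, n_teams + 1)) * n_matches,
        }
    )
    profiles = pd.DataFrame(
        {
            "match_id": np.repeat([k[0] for k in keys], 4),
            "team_id": np.repeat([k[1] for k in keys], 4),
            "player_id": [f"{k[1]}-p{j}" for k in keys for j in range(4)],
            "rank_points": np.tile([1.0, 2.0, 3.0, 4.0], len(keys)),
        }
    )
    return behavior, risk, ranks, profiles


def test_assemble_records_counts_and_experience():
    b, r, rk, pr = _toy_inputs()
    rec = assemble_records(b, r, rk, pr)
    assert len(rec) == 15
    assert (rec["team_experience"] == 2.5).all()  # mean of {1,2,3,4}


def test_assemble_records_names_orphans():
    b, r, rk, pr = _toy_inputs()
    r2 = r.iloc[1:]
    with pytest.raises(JoinError, match="m0"):
        assemble_records(b, r2, rk, pr)


class TestZScoreFilter:
    def test_identical_values_keep_everything(self):
        df = pd.DataFrame({"x": [5.0] * 10})
        with pytest.warns(UserWarning, match="zero variance"):
            kept, report = zscore_filter(df, ["x"])
        assert len(kept) == 10 and report.empty

    def test_postcondition_no_extreme_z_wrt_original_moments(self):
        x = np.concatenate([rng.normal(size=200), [40.0, -35.0]])
        df = pd.DataFrame({"x": x})
        kept, report = zscore_filter(df, ["x"], z_max=3)
        mu, sd = x.mean(), x.std()
        assert (np.abs((kept["x"] - mu) / sd) <= 3).all()
        assert set(report["variable"]) == {"x"}
        assert len(kept) + len(df.loc[report["row"].unique()]) == len(df)

    def test_planted_outlier_recovered_from_simulator(self):
        """In an otherwise homogeneous cohort the hacker-style coordinate
        spike inflates collab_low past 3 SD and exactly the spiked
        team-matches are dropped."""
        from squadperf.simulate import HazardParams, ShrinkSchedule

        cfg = small_config(
            seed=23, n_matches=4, outlier_rate=0.04,
            cohesion_sigma_cm=3000.0, member_sigma_spread=0.0,
            schedule=ShrinkSchedule(cap_s=400.0),
            hazard=HazardParams(alpha=-12.0, alpha_slope=0.0),
        )
        sim = simulate_cohort(cfg)
        behavior, _, _ = compute_features(sim)
        spiked = sim.ground_truth.loc[
            sim.ground_truth["outlier"], ["match_id", "team_id"]
        ]
        assert len(spiked) >= 1
        kept, report = zscore_filter(behavior, ["collab_low"], z_max=3)
        dropped = behavior.loc[report["row"].unique(), ["match_id", "team_id"]]
        assert set(map(tuple, dropped.values)) == set(map(tuple, spiked.values))


class TestConjointExperience:
    def test_disjoint_rosters_give_zero(self):
        rosters = pd.DataFrame(
            {
                "match_id": ["a"] * 4 + ["b"] * 4,
                "team_id": ["a-t0"] * 4 + ["b-t0"] * 4,
                "player_id": [f"p{i}" for i in range(8)],
            }
        )
        pct = conjoint_experience(rosters)
        assert all(v == 0.0 for v in pct.values())

    def test_recurring_quartet(self):
        """One identical 4-player team across two 100-player matches."""
        rows = []
        for m in ("a", "b"):
            for j in range(4):
                rows.append({"match_id": m, "team_id": f"{m}-t0", "player_id": f"q{j}"})
            for j in range(96):
                rows.append(
                    {"match_id": m, "team_id": f"{m}-t{1 + j // 4}",
                     "player_id": f"{m}-x{j}"}
                )
        pct = conjoint_experience(pd.DataFrame(rows))
        expected = 4 / 196 * 100
        assert pct["quartet_pct"] == pytest.approx(expected)
        assert pct["triad_pct"] == pytest.approx(expected)
        assert pct["dyad_pct"] == pytest.approx(expected)
        assert pct["overall_pct"] == pytest.approx(expected)

    def test_overall_bounds_dominate_levels(self):
        n_players, n_matches = 30, 4
        rows = [
            {
                "match_id": f"m{m}",
                "team_id": f"m{m}-t{i // 4}",
                "player_id": f"p{p}",
            }
            for m in range(n_matches)
            for i, p in enumerate(rng.choice(n_players, size=16, replace=False))
        ]
        pct = conjoint_experience(pd.DataFrame(rows))
        assert 0 <= pct["overall_pct"] <= 100
        assert pct["overall_pct"] >= max(
            pct["dyad_pct"], pct["triad_pct"], pct["quartet_pct"]
        )
        assert pct["dyad_pct"] >= pct["triad_pct"] >= pct["quartet_pct"]


class TestMatchControls:
    def test_single_team_match_controls_equal_own_values(self):
        b, r, rk, pr = _toy_inputs(n_matches=1, n_teams=1)
        rec = assemble_records(b, r, rk, pr)
        out = match_controls(rec)
        assert out["mean_max_dist"].iloc[0] == pytest.approx(out["collab_low"].iloc[0])
        assert out["mean_min_dist"].iloc[0] == pytest.approx(out["collab_high"].iloc[0])
        assert out["mean_sd_dist"].iloc[0] == pytest.approx(out["sd_dist"].iloc[0])

    def test_controls_match_groupby_oracle_and_permutation(self):
        b, r, rk, pr = _toy_inputs()
        rec = assemble_records(b, r, rk, pr)
        out = match_controls(rec)
        for mid, grp in rec.groupby("match_id"):
            manual = sum(grp["collab_low"]) / len(grp)  # independent loop oracle
            got = out.loc[out["match_id"] == mid, "mean_max_dist"].unique()
            assert len(got) == 1 and got[0] == pytest.approx(manual)
        shuffled = match_controls(rec.sample(frac=1, random_state=0))
        merged = out.merge(
            shuffled[["match_id", "team_id", "mean_max_dist"]],
            on=["match_id", "team_id"], suffixes=("", "_s"),
        )
        assert np.allclose(merged["mean_max_dist"], merged["mean_max_dist_s"])


def test_strategy_proxy_thresholds():
    assert strategy_proxy(0.0, 100.0) == "exploration"
    assert strategy_proxy(100.0, 100.0) == "exploitation"
    assert strategy_proxy(50.0, 100.0) == "ambidexterity"
    with pytest.raises(ValueError):
        strategy_proxy(1.0, 0.0)


class TestExperienceStrata:
    def test_separated_clusters_assign_exactly(self):
        values = [0, 0, 0, 5, 5, 5, 10, 10, 10]
        sa = experience_strata(values, seed=0)
        assert list(sa.labels) == ["LOW"] * 3 + ["MEDIUM"] * 3 + ["HIGH"] * 3
        assert sa.sizes == {"LOW": 3, "MEDIUM": 3, "HIGH": 3}

    def test_labels_invariant_to_input_order(self):
        values = rng.uniform(0, 10, size=60)
        sa = experience_strata(values, seed=1)
        perm = rng.permutation(60)
        sa2 = experience_strata(values[perm], seed=1)
        assert list(np.asarray(sa.labels)[perm]) == list(sa2.labels)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            experience_strata([1.0, 1.0, 2.0], k=3)

    def test_mixture_recovery_at_printed_stratum_means(self):
        """Centers near 0.013 / 3.358 / 4.914 and >=99% correct assignment."""
        comp = rng.integers(0, 3, size=600)
        mus = np.array([0.013, 3.358, 4.914])
        x = np.maximum(0.0, mus[comp] + 0.25 * rng.normal(size=600))
        sa = experience_strata(x, seed=2)
        assert np.allclose(sa.centers, mus, atol=0.35)
        want = np.array(["LOW", "MEDIUM", "HIGH"])[comp]
        assert (sa.labels == want).mean() >= 0.99


def test_prepare_cohort_report_bookkeeping(small_cohort):
    behavior, risk, _ = compute_features(small_cohort)
    cohort, report = prepare_cohort(
        behavior, risk,
        ranks_table(small_cohort.matches), profiles_table(small_cohort.matches),
        seed=3,
    )
    assert report["n_input"] == report["n_kept"] + report["n_dropped"]
    assert sum(report["stratum_sizes"].values()) == report["n_kept"]
    assert set(cohort["stratum"]) <= {"LOW", "MEDIUM", "HIGH"}
    assert {"mean_max_dist", "mean_min_dist", "mean_sd_dist", "match_mean_risk"} <= set(
        cohort.columns
    )
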