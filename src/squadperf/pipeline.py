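"""End-to-end pipeline: simulate -> features -> prep -> fit -> report.

A run is driven by a :class:`RunConfig` (YAML-serializable, one global
seed).  Each stage writes its table under the run directory and the run
manifest records config, derived seeds, package version and row counts, so
a manifest suffices to reproduce every number exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import DEFAULT_EPS_CM, behavior_table, write_behavior_csv
from .cohort import prepare_cohort
from .ordinal import (
    DEFAULT_TERMS,
    ModelSpec,
    OrdinalFit,
    fit_interaction,
    fit_logistic_topk,
    fit_ordinal,
    fit_quadratic,
    fit_stratified,
    predicted_vs_observed,
)
from .risk import risk_table, write_heatmap
from .simulate import (
    CohortResult,
    HazardParams,
    ShrinkSchedule,
    SimulationConfig,
    simulate_cohort,
)
from .telemetry import location_table, write_telemetry

DEFAULT_MODELS = ("full1", "full2", "strata", "interaction", "top5", "top10")


@dataclass
class RunConfig:
    """All pipeline parameters: the simulator config plus the analysis
    constants (epsilon 100 m, 10 m cells, Z threshold 3, k = 3 strata,
    median risk quantiles)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    eps_m: float = 100.0
    cell_m: float = 10.0
    z_max: float = 3.0
    k_strata: int = 3
    q_low: float = 0.5
    q_high: float = 0.5
    models: tuple[str, ...] = DEFAULT_MODELS
    min_stratum_rows: int = 200
    strategy_mix: bool = False
    write_telemetry_files: bool = True
    seed: int | None = None  # None: use simulation.seed

    def __post_init__(self):
        if self.seed is not None:
            # One global seed fans out to per-stage seeds (recorded in the
            # manifest): child 0 drives the simulator, child 1 the K-means.
            ss = np.random.SeedSequence(self.seed)
            sim_seed, km_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
            self.simulation = dataclasses.replace(self.simulation, seed=sim_seed)
            self._kmeans_seed = km_seed
        else:
            self._kmeans_seed = int(self.simulation.seed) % 2**31
        for m in self.models:
            if m not in DEFAULT_MODELS:
                raise ValueError(f"unknown model {m!r}; choose from {DEFAULT_MODELS}")

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("_kmeans_seed", None)
        d["models"] = list(self.models)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = yaml.safe_load(text)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            hazard = sim.pop("hazard", {})
            schedule = sim.pop("schedule", {})
            if isinstance(schedule, dict) and schedule.get("trigger_diameters"):
                schedule["trigger_diameters"] = tuple(schedule["trigger_diameters"])
            if isinstance(sim.get("hotspot_centers"), list):
                sim["hotspot_centers"] = tuple(tuple(h) for h in sim["hotspot_centers"])
            if isinstance(sim.get("experience_mixture"), list):
                sim["experience_mixture"] = tuple(
                    tuple(c) for c in sim["experience_mixture"]
                )
            for key in ("landing_risk_preference", "cohesion_sigma_cm", "experience_mean"):
                if isinstance(sim.get(key), list):
                    sim[key] = tuple(sim[key])
            sim = SimulationConfig(
                hazard=HazardParams(**hazard) if isinstance(hazard, dict) else hazard,
                schedule=ShrinkSchedule(**schedule) if isinstance(schedule, dict) else schedule,
                **sim,
            )
        if isinstance(d.get("models"), list):
            d["models"] = tuple(d["models"])
        return cls(simulation=sim, **d)


def _plain(obj):
    """Make a nested structure YAML-safe (tuples -> lists, numpy -> python)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def ranks_table(matches) -> pd.DataFrame:
    rows = [
        {"match_id": m.meta.match_id, "team_id": t, "final_rank": r}
        for m in matches
        for t, r in m.final_ranks.items()
    ]
    return pd.DataFrame(rows, columns=["match_id", "team_id", "final_rank"])


def profiles_table(matches) -> pd.DataFrame:
    rows = []
    for m in matches:
        team_of = {}
        for s in m.states:
            if s.player_id not in team_of:
                team_of[s.player_id] = s.team_id
        for p in m.profiles:
            rows.append(
                {
                    "match_id": m.meta.match_id,
                    "team_id": team_of.get(p.player_id),
                    "player_id": p.player_id,
                    "rank_points": p.rank_points,
                }
            )
    return pd.DataFrame(rows, columns=["match_id", "team_id", "player_id", "rank_points"])


# ---------------------------------------------------------------------------
# Stage drivers (in-memory; run_pipeline adds the file layer)
# ---------------------------------------------------------------------------

def compute_features(cohort_sim: CohortResult, eps_m: float = 100.0,
                     q_low: float = 0.5, q_high: float = 0.5):
    """Behavior and risk feature tables for a simulated cohort."""
    matches = cohort_sim.matches
    tables = {m.meta.match_id: location_table(m) for m in matches}
    durations = {m.meta.match_id: m.meta.duration_s for m in matches}
    behavior = behavior_table(tables, durations, eps_cm=eps_m * 100.0)
    risk = risk_table(matches, cohort_sim.reference_heatmap, tables, q_low, q_high)
    return behavior, risk, tables


def analyze_cohort(
    cohort: pd.DataFrame,
    models=DEFAULT_MODELS,
    min_stratum_rows: int = 200,
    base_terms=DEFAULT_TERMS,
):
    """Fit the requested model battery on a prepared cohort table."""
    cohort = cohort.copy()
    cohort["time_high_risk_min"] = cohort["time_high_risk_s"] / 60.0
    cohort["time_low_risk_min"] = cohort["time_low_risk_s"] / 60.0
    # A degenerate cohort (e.g. a tiny map with a sparse reference heatmap)
    # can produce constant feature columns; drop them rather than fail.
    usable = []
    for t in base_terms:
        if cohort[t].std(ddof=0) > 0:
            usable.append(t)
        else:
            warnings.warn(f"dropping zero-variance model term {t!r}")
    spec = ModelSpec(terms=tuple(usable))
    fits: dict[str, object] = {}
    if "full1" in models:
        fits["full1"] = fit_ordinal(cohort, spec)
    if "full2" in models:
        fits["full2"] = fit_quadratic(cohort, spec)
    if "strata" in models:
        strat = fit_stratified(
            cohort,
            dataclasses.replace(spec, quadratic_terms=("share_high",)),
            min_rows=min_stratum_rows,
        )
        for s, f in strat.items():
            fits[f"stratum_{s}"] = f
    if "interaction" in models:
        fits["interaction"] = fit_interaction(cohort, spec)
    for name, k in (("top5", 5), ("top10", 10)):
        if name in models:
            fits[name] = fit_logistic_topk(cohort, spec, k=k)
    return fits, cohort


def fit_to_dict(name: str, fit) -> dict:
    d = {
        "model": name,
        "n": fit.n,
        "logl": fit.logl,
        "logl_null": fit.logl_null,
        "converged": fit.converged,
        "coefficients": {
            t: {
                "estimate": float(fit.params[t]),
                "se": float(fit.bse[t]),
                "ci_low": float(fit.ci_low[t]),
                "ci_high": float(fit.ci_high[t]),
                "p": float(fit.pvalues[t]),
            }
            for t in fit.params.index
        },
    }
    if isinstance(fit, OrdinalFit):
        d["r2_ml"] = fit.r2_ml
        d["thresholds"] = fit.thresholds.tolist()
        d["centers"] = fit.centers
        if fit.vif is not None:
            d["vif"] = {k: (None if not np.isfinite(v) else float(v))
                        for k, v in fit.vif.items()}
    else:
        d["k"] = fit.k
        d["separation"] = fit.separation
    return d


def coefficient_table(fits: dict) -> pd.DataFrame:
    """Terms x models table of 'estimate (ci_low, ci_high)' strings, shaped
    like a journal coefficient table."""
    cols = {}
    for name, fit in fits.items():
        col = {}
        for t in fit.params.index:
            col[t] = (
                f"{fit.params[t]:.3f} ({fit.ci_low[t]:.3f}, {fit.ci_high[t]:.3f})"
                + _stars(fit.pvalues[t])
            )
        cols[name] = col
    return pd.DataFrame(cols).fillna("")


def _stars(p: float) -> str:
    return "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.1 else ""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run every stage, writing all artifacts under ``out_dir``.

    Re-running with the same config reproduces every number exactly; a
    stage failure halts with the stage name, preserving partial outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _plain(config.to_dict()),
        "config_sha256": hashlib.sha256(config.to_yaml().encode()).hexdigest(),
        "version": __version__,
        "seeds": {
            "global": config.seed,
            "simulation": config.simulation.seed,
            "kmeans": config._kmeans_seed,
        },
        "row_counts": {},
    }

    stage = "simulate"
    try:
        sim = simulate_cohort(config.simulation)
        if config.write_telemetry_files:
            tdir = out / "telemetry"
            tdir.mkdir(exist_ok=True)
            for m in sim.matches:
                write_telemetry(m, tdir / f"{m.meta.match_id}.jsonl")
        sim.ground_truth.to_csv(out / "ground_truth.csv", index=False)
        write_heatmap(sim.reference_heatmap, out / "reference_heatmap.csv")
        manifest["row_counts"]["matches"] = len(sim.matches)
        manifest["row_counts"]["teams_simulated"] = len(sim.ground_truth)

        stage = "features"
        behavior, risk, _tables = compute_features(
            sim, eps_m=config.eps_m, q_low=config.q_low, q_high=config.q_high
        )
        write_behavior_csv(behavior, out / "behavior.csv")
        behavior.to_csv(out / "behavior_full.csv", index=False)
        risk.to_csv(out / "risk.csv", index=False)
        ranks = ranks_table(sim.matches)
        profiles = profiles_table(sim.matches)
        ranks.to_csv(out / "ranks.csv", index=False)
        profiles.to_csv(out / "profiles.csv", index=False)
        manifest["row_counts"]["behavior_rows"] = len(behavior)
        manifest["row_counts"]["risk_rows"] = len(risk)

        stage = "prep"
        cohort, prep_report = prepare_cohort(
            behavior,
            risk,
            ranks,
            profiles,
            z_max=config.z_max,
            k_strata=config.k_strata,
            seed=config._kmeans_seed,
            strategy_mix=config.strategy_mix,
        )
        cohort.to_csv(out / "cohort.csv", index=False)
        (out / "prep_report.json").write_text(json.dumps(_plain(prep_report), indent=2))
        manifest["row_counts"]["cohort_in"] = prep_report["n_input"]
        manifest["row_counts"]["cohort_kept"] = prep_report["n_kept"]
        manifest["row_counts"]["cohort_dropped"] = prep_report["n_dropped"]

        stage = "fit"
        fits, cohort_aug = analyze_cohort(
            cohort, models=config.models, min_stratum_rows=config.min_stratum_rows
        )
        fdir = out / "fits"
        fdir.mkdir(exist_ok=True)
        for name, fit in fits.items():
            d = fit_to_dict(name, fit)
            if isinstance(fit, OrdinalFit):
                pvo = predicted_vs_observed(fit, cohort_aug)
                d["calibration"] = (
                    pvo.groupby("observed")["expected"].mean().round(6).to_dict()
                )
            (fdir / f"{name}.json").write_text(json.dumps(_plain(d), indent=2))
        ord_fits = {n: f for n, f in fits.items() if isinstance(f, OrdinalFit)}
        coefficient_table(ord_fits).to_csv(fdir / "coefficient_table.csv")
        manifest["row_counts"]["models_fit"] = len(fits)

        stage = "report"
        (out / "manifest.json").write_text(json.dumps(_plain(manifest), indent=2))
        make_report(out)
    except Exception as exc:  # noqa: BLE001 - halt with stage name
        (out / "manifest.json").write_text(json.dumps(_plain(manifest), indent=2))
        raise StageError(stage, exc) from exc
    return out


def make_report(run_dir) -> Path:
    """Render a summary document (markdown + figures) from a run's own
    artifacts — numbers are read from the fit JSONs, never recomputed."""
    run = Path(run_dir)
    fdir = run / "fits"
    if not fdir.exists():
        raise FileNotFoundError(f"no fits/ under {run}; run the fit stage first")
    fits = {
        p.stem: json.loads(p.read_text())
        for p in sorted(fdir.glob("*.json"))
    }
    cohort = pd.read_csv(run / "cohort.csv")

    lines = ["# Run report", ""]
    lines.append("## Model coefficients")
    lines.append("")
    table_path = fdir / "coefficient_table.csv"
    if table_path.exists():
        tab = pd.read_csv(table_path, index_col=0)
        lines.append(tab.to_markdown())
        lines.append("")
    lines.append("## Fit statistics")
    lines.append("")
    for name, d in fits.items():
        if "r2_ml" in d:
            lines.append(
                f"- {name}: n={d['n']}, logL={d['logl']:.2f}, r2ML={d['r2_ml']:.4f},"
                f" converged={d['converged']}"
            )
        else:
            lines.append(
                f"- {name}: n={d['n']}, logL={d['logl']:.2f} (top-{d.get('k')}"
                f" logistic), separation={d.get('separation')}"
            )
    lines.append("")

    strata_fits = {n: d for n, d in fits.items() if n.startswith("stratum_")}
    if strata_fits:
        lines.append("## Stratified quadratic effect of high interdependence")
        lines.append("")
        for name, d in sorted(strata_fits.items()):
            co = d["coefficients"].get("share_high_sq")
            if co:
                lines.append(
                    f"- {name}: quadratic estimate {co['estimate']:.3f} "
                    f"({co['ci_low']:.3f}, {co['ci_high']:.3f})"
                )
            else:
                lines.append(f"- {name}: no quadratic term (panel omitted)")
        lines.append("")

    if "risk_category" in cohort.columns:
        counts = cohort["risk_category"].value_counts().sort_index()
        lines.append("## Risk-category counts")
        lines.append("")
        for cat, cnt in counts.items():
            lines.append(f"- category {cat:+d}: {cnt} teams")
        lines.append("")

    _plot_report_figures(run, fits, strata_fits, cohort)
    path = run / "report.md"
    path.write_text("\n".join(lines))
    return path


def _plot_report_figures(run: Path, fits: dict, strata_fits: dict, cohort: pd.DataFrame):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # Predicted vs observed calibration per ordinal model.
    cal_fits = {n: d for n, d in fits.items() if "calibration" in d}
    if cal_fits:
        fig, axes = plt.subplots(
            1, len(cal_fits), figsize=(4 * len(cal_fits), 3.5), squeeze=False
        )
        for ax, (name, d) in zip(axes[0], sorted(cal_fits.items())):
            obs = [float(k) for k in d["calibration"]]
            exp = list(d["calibration"].values())
            ax.scatter(obs, exp, s=12)
            lim = [min(obs), max(obs)]
            ax.plot(lim, lim, lw=1, color="gray")
            ax.set_title(name)
            ax.set_xlabel("observed rank")
            ax.set_ylabel("expected rank")
        fig.tight_layout()
        fig.savefig(run / "predicted_vs_observed.png", dpi=100)
        plt.close(fig)

    # Stratified effect of high-interdependence share on the linear predictor.
    if strata_fits:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        s = np.linspace(0, 1, 101)
        for name, d in sorted(strata_fits.items()):
            co = d["coefficients"]
            if "share_high" not in co:
                continue
            c = d.get("centers", {}).get("share_high", 0.0)
            y = co["share_high"]["estimate"] * s
            if "share_high_sq" in co:
                y = y + co["share_high_sq"]["estimate"] * (s - c) ** 2
            ax.plot(s, y, label=name.replace("stratum_", ""))
        ax.set_xlabel("share of time in HIGH interdependence")
        ax.set_ylabel("rank linear predictor (lower = better)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(run / "stratified_effect.png", dpi=100)
        plt.close(fig)

    if "risk_category" in cohort.columns:
        fig, ax = plt.subplots(figsize=(4, 3))
        cohort["risk_category"].value_counts().sort_index().plot.bar(ax=ax)
        ax.set_xlabel("risk category")
        ax.set_ylabel("teams")
        fig.tight_layout()
        fig.savefig(run / "risk_categories.png", dpi=100)
        plt.close(fig)
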