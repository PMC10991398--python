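# squadperf

Team behavioral interdependence, collaboration, risk-taking and
performance in squad-based battle-royale matches.

Competitive battle-royale telemetry records every player's position every
10 seconds, each parachute landing, season experience scores, and the
final team ranking. `squadperf` turns that telemetry into team-level
behavioral features and models how they predict the final rank — in
particular the curvilinear ("too much of a good thing") effect of
behavioral interdependence and how player experience moderates it. It is
aimed at computational behavioral scientists who want a tested, seeded,
end-to-end pipeline: a synthetic match simulator with planted effects
provides ground truth, so every stage can be validated by parameter
recovery rather than by eyeballing.

## The model

Per team-match, the pipeline measures:

- **Interdependence state shares** — at each timepoint the team's alive
  members are clustered with DBSCAN (minPts = 1, ε = 100 m, i.e. ε-graph
  connected components): HIGH = one cluster, LOW = all singletons,
  MEDIUM = otherwise; aggregated to time shares `s_high, s_med, s_low`.
- **Collaboration** — per-timepoint farthest and closest within-team pair
  distance, as `log1p(d / max(0.1, remaining-time fraction))` to undo the
  shrinking play area, time-averaged ("loose" and "tight" collaboration).
- **Risk** — landing counts of reference players on a 10 × 10 m grid give
  each cell a riskiness; teams get max/min member landing risk and time
  spent in high-risk cells (above the median nonzero cell).

Final rank (1 = winner) is modelled with a proportional-odds
cumulative-logit model,

    P(rank ≤ j | x) = logistic(θ_j − x·β),

so a negative β means better placement. The battery includes the full
linear model, a quadratic model (centered squared shares), experience
strata fitted separately (Aiken–West simple slopes via K-means strata of
team experience), a share × experience interaction model, and top-5/top-10
logistic robustness checks, with r2ML and VIF diagnostics.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
cohort (30 matches × 25 teams of 4 on Erangel, defaults = study
conditions):

```
python analysis/01_simulate_cohort.py
python analysis/02_behavior_features.py
python analysis/03_risk_features.py
python analysis/04_prepare_cohort.py
python analysis/05_fit_models.py
python analysis/06_report.py
```

which prints (abridged):

```
simulated 30 matches / 750 team-rows (134 cap survivors)
planted q_eff range: [-12.72, -0.09] (negative = inverted-U pressure, ~0 = linear)
kept 697/750 rows (53 dropped at |z|>3)
stratum sizes {'LOW': 397, 'MEDIUM': 196, 'HIGH': 104}, centers [0.097, 3.405, 5.098]
LOW    n= 397 r2ML=0.898 quadratic(share_high) +3.86 [+1.06, +6.66]
MEDIUM n= 196 r2ML=0.893 quadratic(share_high) +4.97 [+0.54, +9.41]
HIGH   n= 104 r2ML=0.915 quadratic(share_high) +0.14 [-6.31, +6.58]
interaction share_high x z_experience: -2.21 (p=0.0000)
```

Read: the generator planted a concave (inverted-U) performance effect of
the high-interdependence share whose curvature attenuates with experience
(`q_eff → 0`). The stratified fits recover exactly that — the LOW-experience
stratum shows a positive rank-scale quadratic (rank is U-shaped in the
share, i.e. performance is inverted-U) with a CI excluding zero, while the
HIGH-experience stratum's quadratic is ≈ 0 with a CI straddling zero, and
the interaction term is negative (more experience → steeper linear benefit
of clustering). The Z-filter, stratum centers (≈ 0.01 / 3.4 / 5.1) and
r2ML values are all computed from the run's own data.

A `squadperf` CLI wraps the same stages (`simulate`, `features behavior`,
`features risk`, `prep`, `fit`, `report`, and all-in-one `run`) over YAML
configs; see `squadperf --help`. The telemetry file format is documented
in `docs/telemetry_schema.md`, the full methods note in `docs/methods.md`.

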