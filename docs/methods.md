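# Methods

This note documents the models and procedures implemented in `squadperf`:
how team behavior is measured from battle-royale telemetry, how the
ordinal performance models are specified and fitted, what the synthetic
match generator emulates, and the numerical and design choices made where
the design was genuinely open.

## The measurement model

**Unit of analysis.** One row per team per match. The outcome is the final
ranking position (1 = winner, larger = worse), an ordinal variable with as
many levels as teams in the match (25 at the defaults).

**Behavioral interdependence.** At every 10-second sample, the alive
members of a team are clustered with DBSCAN at `minPts = 1` and
`eps = 100 m`. With `minPts = 1` no point can be noise, and the clustering
is exactly the connected components of the graph joining members within
100 m — the implementation computes components directly
(`scipy.sparse.csgraph`) and the test suite verifies equivalence against
both a union-find oracle and scikit-learn's DBSCAN. A timepoint is HIGH
when all alive members fall in one cluster, LOW when every member is a
singleton, MEDIUM otherwise. Because ε-graph components chain, three
players in a 90 m-spaced line are one cluster even though the endpoints
are 180 m apart; this is forced by DBSCAN with `minPts = 1` and is
accepted as the operational definition.

Per-timepoint states are aggregated to **time shares** `share_high`,
`share_med`, `share_low` in [0, 1] (fractions of evaluated timepoints).
The aggregation to shares is a design choice: the regression enters all
state variables simultaneously, which rules out a single categorical
coding, and shares are the minimal continuous encoding. Timepoints with
fewer than two alive members are excluded (interdependence and
collaboration are undefined for singletons); dead members are dropped from
the point set, not imputed, because the telemetry dialect truncates
locations at death.

**Collaboration (tight/loose).** All C(n,2) within-team pair distances are
computed per timepoint, log-transformed and normalized for the shrinking
play area:

    nd = log1p( d_cm / max(0.1, (duration − t) / duration) )

Dividing by the remaining-time fraction up-weights late-match distances in
proportion to elapsed time, offsetting the mechanical contraction of
distances as the circle closes; the floor 0.1 caps the late-game
multiplier at 10×. `log1p` rather than `log` keeps coincident players
(d = 0) finite at 0 — coincident players are legitimate. `collab_low`
("loose collaboration") is the time-average of the per-timepoint **maximum**
normalized distance, `collab_high` ("tight collaboration") of the
**minimum**; by construction `collab_high ≤ collab_low`. All behavior
features depend on coordinates only through pairwise distances, so they
are invariant under rigid motions of the map (tested to 1e-9).

**Risk.** Each map is divided into 10 × 10 m cells (816×816 cells on
Miramar/Erangel, 408×408 on Sanhok, 204×204 on Karakin; half-open cells,
the far map edge belongs to the last cell). The riskiness of a cell is the
number of reference-cohort parachute landings in it; the reference heatmap
is built from a **held-out** landing sample (a separate seeded draw from
the landing law), never from the analysis cohort, to avoid self-counting
leakage. A team's `landing_risk_high`/`landing_risk_low` are the max/min
cell counts over its members' landings. For overtime risk, a cell is
"high-risk" iff its count exceeds the **median of nonzero cells** — the
cutoff is not prescribed anywhere, and the median of nonzero cells is the
simplest scale-free choice. `time_high_risk_s` accumulates 10 s for every
sampled point the most risk-seeking member spends in a high-risk cell;
`time_low_risk_s` takes the max over members of low-risk time (the member
who most exhibits risk-avoidance — the max/min pairing is ambiguous in
principle and is switchable in code). The cohort-level `risk_category`
(−1/0/+1) thresholds `time_high_risk_s` at configurable quantiles,
defaulting to the median on both sides so that 0 holds only exact-median
ties; three populated classes require `q_low < q_high`.

**Controls and filtering.** Team experience is the mean of member season
rank points. Match-level controls are means over the match's teams of the
collaboration extremes, of each team's pooled pair-distance SD, and of
overtime risk. An optional exploration/ambidexterity/exploitation strategy
mix (behind the `strategy_mix` flag) is a documented proxy — the fraction
of evaluated time in high-risk cells cut at 1/3 and 2/3 — because no
operational definition of those labels exists for this data. Outliers
(hackers, bots, bugs) are removed by a **single-pass** Z-score filter: a
row is dropped iff |x − mean| > 3·SD for any filtered feature, with
moments computed once on the unfiltered table (no re-estimation after
drops; the simplest reading, stated in the prep report). Conjoint
experience is counted on player identities: a player has dyadic conjoint
experience if some teammate recurs with them across two matches, triadic
if two teammates recur together, quartet if three; `overall` is any. The
definitions are inclusive (quartet ⊆ triad ⊆ dyad), so
`overall ≥ max(dyad, triad, quartet)`.

**Experience strata.** Teams are stratified LOW/MEDIUM/HIGH by 1-D K-means
(k = 3, 10 restarts, fixed seed), clusters relabeled by ascending center.
Stratification is at the team level: the analysis unit is the team-match
row, and stratified model sizes must sum to the cohort size. The
experience scale is treated as an arbitrary non-negative score; the
synthetic generator draws it from a three-component mixture with centers
0.013 / 3.358 / 4.914 and weights 0.607 / 0.218 / 0.175, matching the
real cohort's published stratum structure.

## The ordinal models

The performance model is a proportional-odds cumulative-logit model

    P(rank ≤ j | x) = logistic(θ_j − x·β),   θ_1 < … < θ_{J−1},

fitted by maximum likelihood (statsmodels `OrderedModel` behind the module
surface; BFGS, gtol 1e−5, max 1000 iterations — recorded in fit metadata).
Because ranks ascend as performance worsens, a **negative coefficient means
better placement**. The logit link is the default for cumulative-link
models and matches odds-style interpretation; no random effects are used
(team-match rows are treated as independent), and no multiple-testing
correction is applied (stars at 0.1/0.05/0.01 are raw Wald p-values).

The three state shares sum to one, so entering all three alongside the
thresholds is exactly collinear; `share_med` is the omitted reference
category in every model, and `fit_ordinal` refuses rank-deficient designs,
naming the collinear terms. Overtime-risk times enter in minutes for
numerical conditioning.

The battery: `full1` (linear), `full2` (adds centered-and-squared shares —
centering reduces collinearity with the linear terms and makes the
quadratic coefficient invariant to constant shifts), the three stratified
quadratic fits (simple slopes by stratification: each stratum is refitted
on its own rows only), the interaction model (share × standardized
experience products, experience entering as a main effect), and top-5 /
top-10 logistic robustness fits. Null log-likelihood is the closed form
Σ n_j log(n_j/n); fit quality is the maximum-likelihood pseudo R²,
`r2ML = 1 − exp((2/n)(logL_null − logL_model))` ∈ [0, 1). VIFs are
computed as 1/(1 − R²_k) from least-squares regressions of each column on
the rest (intercept included; exact collinearity reports ∞).

**Recovery definitions.** "Inverted-U recovered in a stratum" means the
rank-scale quadratic coefficient on `share_high` is positive with its 95%
Wald CI excluding zero (positive rank-scale curvature = concave
performance). "Flattened to linear" is a point-null check and uses the
stricter 99% Wald CI covering zero, so that a sampling fluctuation at a
truly-zero curvature is not flagged as a U-shape. The linear trend is
reported alongside but not gated.

## The synthetic match generator

The generator emulates 100-player / 25-team squad matches on square maps
(Miramar/Erangel 8.16 km, Sanhok 4.08 km, Karakin 2.04 km sides), 10-s
location sampling, hotspot-concentrated landings, the shrinking play area,
and a team-level elimination process with planted effects. Defaults are
the study conditions; every stochastic step flows from one `SeedSequence`,
so a cohort is bit-reproducible from its seed and any prefix of matches is
independent of the rest.

**Play circle.** Initial radius is the map half-diagonal. After a 300 s
hold the radius contracts at 2280 cm/s; at each trigger diameter the
contraction pauses for 200 s; the cycle continues until the 1800 s cap.
Trigger diameters default to geometric halving of the initial diameter
(the true trigger values are unpublished and are free parameters here);
with the defaults the radius reaches its floor before the cap.

**Landings.** Each team draws an anchor from a five-hotspot Gaussian
mixture (σ = 60 m) with probability equal to its
`landing_risk_preference` ∈ [0, 1], else uniformly over the map; members
scatter around the anchor with the team's cohesion σ. Coordinates are
clipped to the map.

**Movement.** Team centroids take Gaussian random-walk steps (60 m per
10 s) and are projected back inside the current circle and the map — an
offset-Gaussian walk, not pathfinding, because the analysis consumes only
distances and cell occupancy. Members are centroid + Gaussian offsets,
resampled each step, radially truncated at 3σ (so every position is inside
circle radius + 3σ). The team cohesion σ is drawn log-uniformly from
1.5 m–600 m so the interdependence shares span their full range, and each
member carries a log-normal dispersion multiplier
(`member_sigma_spread = 1.2`): squads have anchors and flankers, so the
farthest-pair collaboration feature varies partly independently of the
co-clustering share. Without that heterogeneity the collab features are a
near-deterministic proxy of σ (VIF ≈ 25–40 against the shares) and the
latent collinearity distorts conditional curvature estimates.

**Elimination.** Every 10 s interval, each alive team is eliminated with
probability `logistic(alpha + alpha_slope·t/T − η)`, where η is a
*performance score* over the team's running features (state shares so far,
collaboration extremes so far, fraction of member-time in high-risk cells,
standardized experience z):

    η = b_high·s_high + b_med·s_med + b_low·s_low
        + q_high·exp(−m_exp·z)·s_high²
        + b_collab_low·(collab_low − 9) + b_collab_high·(collab_high − 8)
        + b_risk·risk_frac

Defaults: alpha −4 (flat in time), b_high 3, b_med 0.3, b_low −1,
q_high −4, m_exp 1.5, b_collab_low 0.25, b_collab_high 0.15, b_risk −0.8.
With `q_high < 0` performance is concave in the high-interdependence
share — an interior optimum, the "too much of a good thing" pattern — and
experience moderates the curvature **multiplicatively**:
`exp(−m_exp·z)` attenuates `q_high` toward zero as experience grows
without ever reversing its sign, so low-experience teams face a strong
inverted U while high-experience teams face a near-linear benefit. (An
additive moderation `q_high + m·z` was rejected because it overshoots zero
inside the high-experience stratum and plants a spurious U-shape there.)
The last team alive gets rank 1; earlier eliminations get worse ranks in
reverse order; cap survivors are ranked by final hazard ascending;
simultaneous eliminations break by team id. Elimination operates on whole
teams — the analysis never needs player-level death order — and location
records stop at elimination.

**Outlier injection.** A separate fixture flag (`outlier_rate`) plants
hacker-style anomalies: one member of a flagged team teleports between
opposite map corners every step, producing feature rows far outside the
cohort distribution for the Z-filter tests.

**What the generator does not emulate.** No combat or loot mechanics, no
per-player kill credit, no moving circle center, no within-match behavior
changes (a team's cohesion regime is fixed), no real map geography —
hotspots are abstract Gaussians. Passing recovery tests therefore shows
that the *pipeline* measures and models what was planted under these
idealized dynamics; it does not validate the behavioral claims on real
telemetry.

## Calibration and known limitations

The elimination process is a discrete-time sequential hazard, not a
proportional-odds model, so the induced rank–feature relationship is
curved even when the hazard is linear in the shares (survival
probabilities accumulate multiplicatively). For this reason the null
calibration of the quadratic and interaction estimators uses outcomes
drawn from an **exact** cumulative-logit model linear in features taken
from a simulated cohort (`simulate_proportional_odds`); there, zero
curvature is true by construction and each 95% CI covers zero at its
nominal rate. Conversely, the planted-moderation recovery runs the whole
pipeline — simulator, features, prep, stratified fits — at 2,000 teams per
replicate.

Problem sizes used by the test suite and the acceptance script (chosen as
sensible desk-scale cohorts): 2,000-team cohorts (80 matches) for planted
recovery, 20 seeded replicates; 500-team cohorts for null calibration, 40
replicates; smaller 8–10-team matches on Karakin for unit tests. The
pseudo-R² of the synthetic cohorts (~0.85) is far above the ~0.35 of real
match data: the generator's features capture nearly all systematic rank
variation, which makes recovery tests sharp but optimistic relative to
field data.

Degenerate inputs are handled explicitly: teams with no timepoint with ≥2
alive members produce an invalid feature row and are excluded; zero-variance
variables are skipped by the Z-filter (with a warning) and pruned from
model terms by the pipeline driver; an all-zero heatmap has no risk
cutoff (error); fewer than k distinct experience values cannot be
stratified (error); non-converged fits are flagged, never silently
returned.
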