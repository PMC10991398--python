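cell_m: 10.0
eps_m: 100.0
k_strata: 3
min_stratum_rows: 50
models:
- full1
- full2
- strata
- interaction
- top5
- top10
q_high: 0.5
q_low: 0.5
seed: null
simulation:
  cohesion_sigma_cm:
  - 1500.0
  - 60000.0
  experience_mean: null
  experience_mixture:
  - - 0.013
    - 0.15
    - 0.607
  - - 3.358
    - 0.5
    - 0.218
  - - 4.914
    - 0.8
    - 0.175
  experience_sd: 0.1
  hazard:
    alpha: -4.0
    alpha_slope: 0.0
    b_collab_high: 0.15
    b_collab_low: 0.25
    b_high: 3.0
    b_low: -1.0
    b_med: 0.3
    b_risk: -0.8
    collab_high_center: 8.0
    collab_low_center: 9.0
    m_exp: 1.5
    q_high: -4.0
  hotspot_centers:
  - - 244800.0
    - 244800.0
    - 0.3
  - - 571200.0
    - 505920.0
    - 0.25
  - - 424320.0
    - 146880.0
    - 0.2
  - - 146880.0
    - 587520.0
    - 0.15
  - - 669120.0
    - 693600.0
    - 0.1
  hotspot_sigma_cm: 6000.0
  landing_risk_preference:
  - 0.0
  - 1.0
  map_name: Erangel
  member_sigma_spread: 1.2
  n_matches: 10
  n_reference_landings: 20000
  n_teams: 25
  outlier_rate: 0.0
  schedule:
    cap_s: 1800.0
    hold0_s: 300.0
    pause_s: 200.0
    shrink_rate_cm_per_s: 2280.0
    trigger_diameters: null
  seed: 0
  step_sigma_cm: 6000.0
  team_size: 4
strategy_mix: false
write_telemetry_files: true
z_max: 3.0
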