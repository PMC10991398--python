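# JSON-Lines match telemetry dialect

One match per file, one JSON object per line, discriminated by
`record_type`. All coordinates are centimeters from the map's south-west
corner (x east, y north); times are seconds from match start. Numbers are
serialized at full precision, so write→read→write is byte-stable.

## Records

### `meta` (exactly one per file)

```json
{"record_type": "meta", "match_id": "m0001", "map_name": "Erangel",
 "map_side_cm": 816000, "n_players": 100, "team_size": 4, "duration_s": 1800.0}
```

- `map_name` ∈ {Miramar, Erangel, Sanhok, Karakin}; `map_side_cm` must be
  816000, 816000, 408000, 204000 respectively.
- `n_players` must be divisible by `team_size`; `duration_s` ≤ 1800.

### `state` (one per player per 10 s sample)

```json
{"record_type": "state", "player_id": "p1", "team_id": "t0",
 "t_s": 120.0, "x_cm": 400000.0, "y_cm": 380000.0, "alive": true}
```

- Per player, `t_s` values form an arithmetic sequence with step 10 s
  (any common offset in [0, 10) is accepted; the simulator uses 0).
- Coordinates must lie in `[0, map_side_cm]`.
- Location records stop at a player's elimination; the final record at
  death time carries `alive: false`. Earlier records are `alive: true`.

### `landing` (exactly one per player)

```json
{"record_type": "landing", "player_id": "p1", "team_id": "t0",
 "x_cm": 250000.0, "y_cm": 260000.0, "t_s": 0.0}
```

### `profile` (one per player)

```json
{"record_type": "profile", "player_id": "p1", "rank_points": 3.41}
```

`rank_points` is the player's season experience score (finite, ≥ 0).

### `rank` (one per team)

```json
{"record_type": "rank", "team_id": "t0", "final_rank": 1}
```

Final ranks must be a permutation of 1..n_teams (1 = winner; ties are
forbidden in the dialect).

## Derived tables

All derived tables are UTF-8 CSV with a header row and `.` decimal
separator. `behavior.csv` has exactly the columns: match_id, team_id,
share_high, share_med, share_low, collab_high, collab_low, n_timepoints.
`risk.csv` has: match_id, team_id, landing_risk_high, landing_risk_low,
time_high_risk_s, time_low_risk_s, risk_category. Heatmaps are (i, j,
count) CSV triplets of nonzero cells plus a `.meta.json` sidecar (map,
cell size, totals).
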