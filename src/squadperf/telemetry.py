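"""Match-telemetry domain types and the JSON-Lines telemetry dialect.

A match is stored as one JSON object per line, discriminated by a
``record_type`` field in ``{meta, state, landing, profile, rank}``.  All
coordinates are in centimeters, origin at the map corner (x east, y north);
player locations are sampled on a 10-second grid.  The full schema is
documented in ``docs/telemetry_schema.md``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Map side length in centimeters, keyed by map name.
MAP_SIDE_CM: dict[str, int] = {
    "Miramar": 816_000,
    "Erangel": 816_000,
    "Sanhok": 408_000,
    "Karakin": 204_000,
}

#: Location sampling interval in seconds.
SAMPLE_INTERVAL_S = 10.0

#: Hard cap on match duration in seconds (30 minutes).
DURATION_CAP_S = 1800.0


class TelemetryError(ValueError):
    """Base class for telemetry dialect errors."""


class ParseError(TelemetryError):
    """A line could not be parsed as a telemetry record."""


class ValidationError(TelemetryError):
    """A parsed match violates a dialect invariant."""


@dataclass(frozen=True)
class MatchMeta:
    """Match-level metadata: map, roster shape and duration."""

    match_id: str
    map_name: str
    map_side_cm: int
    n_players: int
    team_size: int = 4
    duration_s: float = DURATION_CAP_S

    def validate(self) -> None:
        if self.map_name not in MAP_SIDE_CM:
            raise ValidationError(
                f"unknown map {self.map_name!r}; expected one of {sorted(MAP_SIDE_CM)}"
            )
        if self.map_side_cm != MAP_SIDE_CM[self.map_name]:
            raise ValidationError(
                f"map_side_cm={self.map_side_cm} does not match {self.map_name} "
                f"({MAP_SIDE_CM[self.map_name]})"
            )
        if self.n_players <= 0 or self.team_size <= 0:
            raise ValidationError("n_players and team_size must be positive")
        if self.n_players % self.team_size != 0:
            raise ValidationError(
                f"n_players={self.n_players} not divisible by team_size={self.team_size}"
            )
        if not (0 < self.duration_s <= DURATION_CAP_S):
            raise ValidationError(
                f"duration_s={self.duration_s} outside (0, {DURATION_CAP_S}]"
            )


@dataclass(frozen=True)
class PlayerState:
    """One sampled player location."""

    player_id: str
    team_id: str
    t_s: float
    x_cm: float
    y_cm: float
    alive: bool = True


@dataclass(frozen=True)
class LandingEvent:
    """Parachute landing location of one player."""

    player_id: str
    team_id: str
    x_cm: float
    y_cm: float
    t_s: float = 0.0


@dataclass(frozen=True)
class PlayerProfile:
    """Season experience (rank points) of one player."""

    player_id: str
    rank_points: float


@dataclass
class MatchTelemetry:
    """All telemetry for one match plus the final team ranking.

    ``final_ranks`` maps team_id to final rank, 1 = winner, strictly
    increasing with worse placement; ties are forbidden in the dialect.
    """

    meta: MatchMeta
    states: list[PlayerState] = field(default_factory=list)
    landings: list[LandingEvent] = field(default_factory=list)
    profiles: list[PlayerProfile] = field(default_factory=list)
    final_ranks: dict[str, int] = field(default_factory=dict)

    @property
    def n_teams(self) -> int:
        return self.meta.n_players // self.meta.team_size

    def validate(self) -> None:
        """Enforce every dialect invariant; raise :class:`ValidationError`."""
        self.meta.validate()
        side = self.meta.map_side_cm
        if not self.states:
            raise ValidationError("match has no player states")

        state_teams = set()
        per_player_t: dict[str, list[float]] = {}
        for s in self.states:
            if not (0.0 <= s.x_cm <= side and 0.0 <= s.y_cm <= side):
                raise ValidationError(
                    f"state for {s.player_id} at t={s.t_s} out of map bounds: "
                    f"({s.x_cm}, {s.y_cm}) not in [0, {side}]^2"
                )
            if s.t_s < 0:
                raise ValidationError(f"negative t_s={s.t_s} for {s.player_id}")
            state_teams.add(s.team_id)
            per_player_t.setdefault(s.player_id, []).append(s.t_s)

        for pid, ts in per_player_t.items():
            ts = sorted(ts)
            if len(set(ts)) != len(ts):
                raise ValidationError(f"duplicate timepoints for player {pid}")
            for a, b in zip(ts, ts[1:]):
                if not math.isclose(b - a, SAMPLE_INTERVAL_S, abs_tol=1e-9):
                    raise ValidationError(
                        f"sampling grid violation for player {pid}: "
                        f"step {b - a} s between t={a} and t={b} (expected "
                        f"{SAMPLE_INTERVAL_S} s)"
                    )

        seen_landing = set()
        for ev in self.landings:
            if ev.player_id in seen_landing:
                raise ValidationError(f"duplicate landing for player {ev.player_id}")
            seen_landing.add(ev.player_id)
            if not (0.0 <= ev.x_cm <= side and 0.0 <= ev.y_cm <= side):
                raise ValidationError(
                    f"landing for {ev.player_id} out of map bounds: "
                    f"({ev.x_cm}, {ev.y_cm})"
                )

        for p in self.profiles:
            if not math.isfinite(p.rank_points) or p.rank_points < 0:
                raise ValidationError(
                    f"rank_points for {p.player_id} must be finite and >= 0"
                )

        n_teams = self.n_teams
        ranks = sorted(self.final_ranks.values())
        if ranks != list(range(1, n_teams + 1)):
            raise ValidationError(
                f"final_ranks must be a permutation of 1..{n_teams}, got {ranks}"
            )
        missing = set(self.final_ranks) - state_teams
        if missing:
            raise ValidationError(
                f"ranked teams never appear in states: {sorted(missing)}"
            )


# ---------------------------------------------------------------------------
# JSON-Lines dialect
# ---------------------------------------------------------------------------

def _meta_record(meta: MatchMeta) -> dict:
    return {
        "record_type": "meta",
        "match_id": meta.match_id,
        "map_name": meta.map_name,
        "map_side_cm": meta.map_side_cm,
        "n_players": meta.n_players,
        "team_size": meta.team_size,
        "duration_s": meta.duration_s,
    }


def write_telemetry(match: MatchTelemetry, path) -> None:
    """Write one match in the JSON-Lines dialect (validates first)."""
    match.validate()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps(_meta_record(match.meta)) + "\n")
        for s in match.states:
            fh.write(
                json.dumps(
                    {
                        "record_type": "state",
                        "player_id": s.player_id,
                        "team_id": s.team_id,
                        "t_s": s.t_s,
                        "x_cm": s.x_cm,
                        "y_cm": s.y_cm,
                        "alive": s.alive,
                    }
                )
                + "\n"
            )
        for ev in match.landings:
            fh.write(
                json.dumps(
                    {
                        "record_type": "landing",
                        "player_id": ev.player_id,
                        "team_id": ev.team_id,
                        "x_cm": ev.x_cm,
                        "y_cm": ev.y_cm,
                        "t_s": ev.t_s,
                    }
                )
                + "\n"
            )
        for p in match.profiles:
            fh.write(
                json.dumps(
                    {
                        "record_type": "profile",
                        "player_id": p.player_id,
                        "rank_points": p.rank_points,
                    }
                )
                + "\n"
            )
        for team_id in sorted(match.final_ranks):
            fh.write(
                json.dumps(
                    {
                        "record_type": "rank",
                        "team_id": team_id,
                        "final_rank": match.final_ranks[team_id],
                    }
                )
                + "\n"
            )


_REQUIRED_FIELDS = {
    "meta": ("match_id", "map_name", "map_side_cm", "n_players", "team_size", "duration_s"),
    "state": ("player_id", "team_id", "t_s", "x_cm", "y_cm", "alive"),
    "landing": ("player_id", "team_id", "x_cm", "y_cm", "t_s"),
    "profile": ("player_id", "rank_points"),
    "rank": ("team_id", "final_rank"),
}


def read_telemetry(path) -> MatchTelemetry:
    """Read and validate one match from the JSON-Lines dialect.

    Raises :class:`ParseError` (with line number) on malformed lines and
    :class:`ValidationError` on invariant violations.
    """
    meta: MatchMeta | None = None
    states: list[PlayerState] = []
    landings: list[LandingEvent] = []
    profiles: list[PlayerProfile] = []
    final_ranks: dict[str, int] = {}

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            if not isinstance(rec, dict) or "record_type" not in rec:
                raise ParseError(f"{path}:{lineno}: missing record_type")
            rtype = rec["record_type"]
            if rtype not in _REQUIRED_FIELDS:
                raise ParseError(f"{path}:{lineno}: unknown record_type {rtype!r}")
            missing = [f for f in _REQUIRED_FIELDS[rtype] if f not in rec]
            if missing:
                raise ParseError(
                    f"{path}:{lineno}: {rtype} record missing fields {missing}"
                )
            try:
                if rtype == "meta":
                    if meta is not None:
                        raise ParseError(f"{path}:{lineno}: duplicate meta record")
                    meta = MatchMeta(
                        match_id=str(rec["match_id"]),
                        map_name=str(rec["map_name"]),
                        map_side_cm=int(rec["map_side_cm"]),
                        n_players=int(rec["n_players"]),
                        team_size=int(rec["team_size"]),
                        duration_s=float(rec["duration_s"]),
                    )
                elif rtype == "state":
                    states.append(
                        PlayerState(
                            player_id=str(rec["player_id"]),
                            team_id=str(rec["team_id"]),
                            t_s=float(rec["t_s"]),
                            x_cm=float(rec["x_cm"]),
                            y_cm=float(rec["y_cm"]),
                            alive=bool(rec["alive"]),
                        )
                    )
                elif rtype == "landing":
                    landings.append(
                        LandingEvent(
                            player_id=str(rec["player_id"]),
                            team_id=str(rec["team_id"]),
                            x_cm=float(rec["x_cm"]),
                            y_cm=float(rec["y_cm"]),
                            t_s=float(rec["t_s"]),
                        )
                    )
                elif rtype == "profile":
                    profiles.append(
                        PlayerProfile(
                            player_id=str(rec["player_id"]),
                            rank_points=float(rec["rank_points"]),
                        )
                    )
                else:  # rank
                    final_ranks[str(rec["team_id"])] = int(rec["final_rank"])
            except (TypeError, ValueError) as exc:
                if isinstance(exc, ParseError):
                    raise
                raise ParseError(f"{path}:{lineno}: bad field value: {exc}") from exc

    if meta is None:
        raise ValidationError(f"{path}: no meta record")
    match = MatchTelemetry(
        meta=meta,
        states=states,
        landings=landings,
        profiles=profiles,
        final_ranks=final_ranks,
    )
    match.validate()
    return match


def location_table(match: MatchTelemetry) -> pd.DataFrame:
    """Flatten states to a table (player_id, team_id, t_s, x_cm, y_cm, alive).

    One row per (player, sampled timepoint), sorted by (t_s, team_id,
    player_id).  Rows stop at a player's elimination (the dialect truncates
    telemetry at death).
    """
    df = pd.DataFrame(
        {
            "player_id": [s.player_id for s in match.states],
            "team_id": [s.team_id for s in match.states],
            "t_s": [s.t_s for s in match.states],
            "x_cm": [s.x_cm for s in match.states],
            "y_cm": [s.y_cm for s in match.states],
            "alive": [s.alive for s in match.states],
        }
    )
    return df.sort_values(["t_s", "team_id", "player_id"], kind="mergesort").reset_index(
        drop=True
    )
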