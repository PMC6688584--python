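"""Tracking and event-stream data model, CSV I/O, kinematics, and stream
consolidation.

Two plain-text interchange formats are supported:

* tracking CSV: ``timestamp,player_id,team_id,x,y`` — one row per player
  per 10 Hz frame, timestamp in float seconds (0.1 s resolution), x/y in
  meters in the field frame.
* transactions CSV: ``timestamp,event_type,player_id,x,y`` — one row per
  coded match event, timestamp in whole seconds, ``event_type`` one of
  ``kick``, ``mark``, ``contested_mark``, ``spoil``; x/y is the inferred
  ball location.

Angle convention: displacement direction is measured clockwise from the
positive y-axis, in ``[0, 2*pi)``.  A displacement of ``(0, +1)`` has
direction 0, ``(+1, 0)`` has direction ``pi/2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TRACKING_COLUMNS",
    "TRANSACTION_COLUMNS",
    "EVENT_TYPES",
    "CONTEST_EVENT_TYPES",
    "KICK",
    "MARK",
    "CONTESTED_MARK",
    "SPOIL",
    "SchemaError",
    "ParseError",
    "FormationError",
    "PlayerState",
    "PlayerTrack",
    "FieldFormation",
    "ConsolidationResult",
    "read_tracking",
    "write_tracking",
    "read_transactions",
    "write_transactions",
    "read_formation",
    "build_tracks",
    "consolidate",
    "compute_velocity",
    "displacement_direction",
    "angle_between",
    "heading_angle",
    "to_relative",
]

TWO_PI = 2.0 * math.pi

#: displacement (m) below which a frame-to-frame step carries no heading
DIRECTION_EPSILON = 1e-6

TRACKING_COLUMNS = ["timestamp", "player_id", "team_id", "x", "y"]
TRANSACTION_COLUMNS = ["timestamp", "event_type", "player_id", "x", "y"]

KICK = "kick"
MARK = "mark"
CONTESTED_MARK = "contested_mark"
SPOIL = "spoil"
EVENT_TYPES = frozenset((KICK, MARK, CONTESTED_MARK, SPOIL))
CONTEST_EVENT_TYPES = frozenset((CONTESTED_MARK, SPOIL))


class SchemaError(ValueError):
    """A required column is missing or a categorical value is unsupported."""


class ParseError(ValueError):
    """A cell could not be parsed; the message carries the file line number."""


class FormationError(ValueError):
    """A formation does not satisfy a player-count requirement."""


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _read_checked(path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna().to_numpy()
        if bad.any():
            row = int(np.argmax(bad))
            raise ParseError(
                f"{path}: line {row + 2}, column {col!r}: "
                f"{df[col].iloc[row]!r} is not numeric"
            )
        df[col] = converted.astype(float)
    return df


def read_tracking(path) -> pd.DataFrame:
    """Read a tracking CSV, validate it, and sort by (player_id, timestamp).

    Timestamps are rounded to the documented 0.1 s resolution.
    """
    df = _read_checked(path, TRACKING_COLUMNS, ["timestamp", "x", "y"])
    df["timestamp"] = df["timestamp"].round(1)
    df = df.sort_values(["player_id", "timestamp"], kind="mergesort")
    return df.reset_index(drop=True)[TRACKING_COLUMNS]


def write_tracking(df: pd.DataFrame, path) -> None:
    """Write tracking rows at the documented precision (0.1 s, mm coords).

    Values already at that precision round-trip bit-exactly through
    :func:`read_tracking`.
    """
    out = df[TRACKING_COLUMNS].copy()
    out["timestamp"] = out["timestamp"].map(lambda v: f"{float(v):.1f}")
    out["x"] = out["x"].map(lambda v: f"{float(v):.3f}")
    out["y"] = out["y"].map(lambda v: f"{float(v):.3f}")
    out.to_csv(path, index=False)


def read_transactions(path) -> pd.DataFrame:
    """Read a transactions CSV; timestamps must be whole seconds."""
    df = _read_checked(path, TRANSACTION_COLUMNS, ["timestamp", "x", "y"])
    bad_type = ~df["event_type"].isin(EVENT_TYPES)
    if bad_type.any():
        row = int(np.argmax(bad_type.to_numpy()))
        raise SchemaError(
            f"{path}: line {row + 2}: unsupported event_type "
            f"{df['event_type'].iloc[row]!r} (expected one of {sorted(EVENT_TYPES)})"
        )
    frac = np.abs(df["timestamp"] - np.round(df["timestamp"]))
    if (frac > 1e-6).any():
        row = int(np.argmax((frac > 1e-6).to_numpy()))
        raise ParseError(f"{path}: line {row + 2}: timestamp is not a whole second")
    df["timestamp"] = np.round(df["timestamp"]).astype(np.int64)
    df = df.sort_values("timestamp", kind="mergesort")
    return df.reset_index(drop=True)[TRANSACTION_COLUMNS]


def write_transactions(df: pd.DataFrame, path) -> None:
    out = df[TRANSACTION_COLUMNS].copy()
    out["timestamp"] = out["timestamp"].map(lambda v: f"{int(round(float(v)))}")
    out["x"] = out["x"].map(lambda v: f"{float(v):.3f}")
    out["y"] = out["y"].map(lambda v: f"{float(v):.3f}")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Kinematic primitives
# ---------------------------------------------------------------------------

def heading_angle(dx: float, dy: float) -> float:
    """Angle of displacement ``(dx, dy)`` clockwise from +y, in [0, 2*pi)."""
    return math.atan2(dx, dy) % TWO_PI


def angle_between(a, b, c) -> float:
    """Angle between vectors AB and BC, in [0, pi].

    Raises ``ValueError`` if either vector is (near) zero length.
    """
    abx, aby = b[0] - a[0], b[1] - a[1]
    bcx, bcy = c[0] - b[0], c[1] - b[1]
    n1 = math.hypot(abx, aby)
    n2 = math.hypot(bcx, bcy)
    if n1 < DIRECTION_EPSILON or n2 < DIRECTION_EPSILON:
        raise ValueError("angle_between: degenerate (zero-length) vector")
    cos_theta = (abx * bcx + aby * bcy) / (n1 * n2)
    return math.acos(max(-1.0, min(1.0, cos_theta)))


@dataclass(frozen=True)
class PlayerState:
    """A player's kinematic snapshot at one instant.

    ``direction`` is clockwise from +y in [0, 2*pi).  When the underlying
    displacement was below the movement epsilon and no earlier heading
    exists, ``direction_defined`` is False and ``direction`` is 0 (the
    player is treated as isotropic downstream).
    """

    player_id: str
    team_id: str | None
    x: float
    y: float
    velocity: float
    direction: float
    velocity_defined: bool = True
    direction_defined: bool = True

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


def to_relative(state: PlayerState, location) -> tuple[float, float]:
    """Express ``location`` in the player's displacement frame.

    The player sits at the origin with their displacement direction mapped
    onto +y, so positive ``rel_y`` is in front of the player.  An undefined
    direction falls back to the field frame (direction 0).
    """
    dx = location[0] - state.x
    dy = location[1] - state.y
    theta = state.direction if state.direction_defined else 0.0
    s, c = math.sin(theta), math.cos(theta)
    return (dx * c - dy * s, dx * s + dy * c)


class PlayerTrack:
    """One player's frames indexed by decisecond for O(log n) time lookup."""

    __slots__ = ("player_id", "team_id", "keys", "x", "y")

    def __init__(self, player_id, timestamps, x, y, team_id=None):
        self.player_id = player_id
        self.team_id = team_id
        keys = np.rint(np.asarray(timestamps, dtype=float) * 10.0).astype(np.int64)
        if keys.size > 1 and np.any(np.diff(keys) <= 0):
            raise ParseError(
                f"player {player_id!r}: timestamps are not strictly increasing"
            )
        self.keys = keys
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)

    def _index(self, t: float) -> int:
        key = int(round(t * 10.0))
        i = int(np.searchsorted(self.keys, key))
        if i < len(self.keys) and self.keys[i] == key:
            return i
        return -1

    def position_at(self, t: float) -> tuple[float, float] | None:
        i = self._index(t)
        if i < 0:
            return None
        return (float(self.x[i]), float(self.y[i]))

    def velocity_at(self, t: float) -> float | None:
        """Speed over the exact 1 s window ending at ``t``; None if either
        endpoint frame is missing."""
        i = self._index(t)
        j = self._index(t - 1.0)
        if i < 0 or j < 0:
            return None
        return math.hypot(self.x[i] - self.x[j], self.y[i] - self.y[j])

    def direction_at(self, t: float) -> tuple[float, bool]:
        """Displacement direction at ``t`` with carry-back.

        Uses the step from the immediately preceding frame; if that step is
        below the movement epsilon the most recent earlier moving step is
        carried.  Returns ``(0.0, False)`` when no moving step exists.
        """
        i = self._index(t)
        if i < 0:
            return (0.0, False)
        for j in range(i, 0, -1):
            if self.keys[j] - self.keys[j - 1] != 1:
                continue
            dx = self.x[j] - self.x[j - 1]
            dy = self.y[j] - self.y[j - 1]
            if math.hypot(dx, dy) >= DIRECTION_EPSILON:
                return (heading_angle(dx, dy), True)
        return (0.0, False)

    def state_at(self, t: float) -> PlayerState | None:
        pos = self.position_at(t)
        if pos is None:
            return None
        v = self.velocity_at(t)
        direction, direction_defined = self.direction_at(t)
        return PlayerState(
            player_id=self.player_id,
            team_id=self.team_id,
            x=pos[0],
            y=pos[1],
            velocity=0.0 if v is None else v,
            direction=direction,
            velocity_defined=v is not None,
            direction_defined=direction_defined,
        )


def compute_velocity(track: PlayerTrack, t: float) -> float | None:
    """Euclidean displacement over the 1 s window ending at ``t`` (m/s)."""
    return track.velocity_at(t)


def displacement_direction(track: PlayerTrack, t: float) -> tuple[float, bool]:
    """Displacement direction (clockwise from +y) at ``t`` and a defined flag."""
    return track.direction_at(t)


def build_tracks(tracking: pd.DataFrame) -> dict[str, PlayerTrack]:
    """Split a tracking frame into per-player :class:`PlayerTrack` objects."""
    tracks: dict[str, PlayerTrack] = {}
    for pid, group in tracking.groupby("player_id", sort=True):
        team = group["team_id"].iloc[0]
        tracks[str(pid)] = PlayerTrack(
            str(pid),
            group["timestamp"].to_numpy(),
            group["x"].to_numpy(),
            group["y"].to_numpy(),
            team_id=str(team),
        )
    return tracks


# ---------------------------------------------------------------------------
# Formations and consolidation
# ---------------------------------------------------------------------------

@dataclass
class FieldFormation:
    """All on-field player states at one instant, plus the inferred ball."""

    time: float
    states: dict[str, PlayerState]
    ball_position: tuple[float, float]
    attacking_team: str | None = None

    def teams(self) -> list[str]:
        return sorted({s.team_id for s in self.states.values() if s.team_id})

    def team_states(self, team_id: str) -> list[PlayerState]:
        return [s for s in self.states.values() if s.team_id == team_id]

    def opponent_of(self, team_id: str) -> str:
        others = [t for t in self.teams() if t != team_id]
        if len(others) != 1:
            raise FormationError(
                f"cannot infer opponent of {team_id!r} from teams {self.teams()}"
            )
        return others[0]

    def validate_counts(self, per_team: int = 18) -> None:
        for team in self.teams():
            n = len(self.team_states(team))
            if n != per_team:
                raise FormationError(
                    f"team {team!r} has {n} on-field players, expected {per_team}"
                )


@dataclass
class ConsolidationResult:
    """Outcome of joining transactions onto 10 Hz tracking frames.

    ``formations`` is keyed by row position in the (sorted) ``transactions``
    frame.  ``unmatched`` lists transactions outside the tracking time range;
    ``incomplete`` lists transactions whose second had at least one player
    untracked (those passages are excluded).
    """

    formations: dict[int, FieldFormation]
    transactions: pd.DataFrame
    unmatched: list[int]
    incomplete: list[int]

    @property
    def n_matched(self) -> int:
        return len(self.formations)


def consolidate(
    tracking: pd.DataFrame,
    transactions: pd.DataFrame,
    tracks: Mapping[str, PlayerTrack] | None = None,
) -> ConsolidationResult:
    """Match each transaction to the tracking frame at the start of its second.

    Transactions carry whole-second timestamps, so each is joined to the
    frame at ``t = floor(second)``.  A transaction whose frame lacks any
    player's position is recorded in ``incomplete`` and excluded; one whose
    second falls outside the tracked range is recorded in ``unmatched``.
    """
    if tracks is None:
        tracks = build_tracks(tracking)
    tx = transactions.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    if not tracks:
        return ConsolidationResult({}, tx, list(range(len(tx))), [])
    t_lo = max(float(tr.keys[0]) / 10.0 for tr in tracks.values())
    t_hi = min(float(tr.keys[-1]) / 10.0 for tr in tracks.values())
    team_of = {pid: tr.team_id for pid, tr in tracks.items()}

    formations: dict[int, FieldFormation] = {}
    unmatched: list[int] = []
    incomplete: list[int] = []
    for i in range(len(tx)):
        t = float(int(tx["timestamp"].iloc[i]))
        if t < t_lo or t > t_hi:
            unmatched.append(i)
            continue
        states: dict[str, PlayerState] = {}
        complete = True
        for pid, track in tracks.items():
            st = track.state_at(t)
            if st is None:
                complete = False
                break
            states[pid] = st
        if not complete:
            incomplete.append(i)
            continue
        formations[i] = FieldFormation(
            time=t,
            states=states,
            ball_position=(float(tx["x"].iloc[i]), float(tx["y"].iloc[i])),
            attacking_team=team_of.get(str(tx["player_id"].iloc[i])),
        )
    return ConsolidationResult(formations, tx, unmatched, incomplete)


FORMATION_COLUMNS = ["player_id", "team_id", "x", "y", "velocity", "direction"]


def read_formation(
    path,
    ball_position: tuple[float, float],
    attacking_team: str | None = None,
    time: float = 0.0,
) -> FieldFormation:
    """Read a standalone formation CSV (``player_id,team_id,x,y,velocity,direction``)."""
    df = _read_checked(path, FORMATION_COLUMNS, ["x", "y", "velocity", "direction"])
    states = {}
    for _, row in df.iterrows():
        pid = str(row["player_id"])
        states[pid] = PlayerState(
            player_id=pid,
            team_id=str(row["team_id"]),
            x=float(row["x"]),
            y=float(row["y"]),
            velocity=float(row["velocity"]),
            direction=float(row["direction"]) % TWO_PI,
        )
    return FieldFormation(
        time=time, states=states, ball_position=ball_position,
        attacking_team=attacking_team,
    )
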