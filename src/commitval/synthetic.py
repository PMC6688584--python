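"""Seeded synthetic match generator with known ground truth.

Players follow mean-reverting trajectories around role anchors on an oval
field.  Plays are injected on a schedule: *contest plays* (kick followed by
a spoil / contested mark at the ball's destination) feed the commitment
pipeline, and *pass plays* (mark -> kick -> mark chains) feed the decision
pipeline.  At each contest, every player within 35 m whose kinematics are
defined draws a commitment from a ground-truth rule; committed players are
steered to within the commitment radius of the contest by contest time and
non-committed players are kept safely outside it, so the pipeline's
extracted labels reproduce the generator's draws exactly.

The ground-truth rule is deliberately *not* in the fitted model's family
(a logistic in the reachability miss, versus a KDE posterior), keeping
recovery tests non-circular: a player moving at speed ``v`` with ``t``
seconds available is most likely to commit to contests near their
velocity-projected point ``(0, gain * v * min(t, horizon))`` in their own
displacement frame, with commitment decaying logistically in the distance
("miss") from that point, and shrinking with time-to-point and speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from scipy.special import expit

from .commitment import OBSERVATION_COLUMNS, fit
from .field import FieldConfig
from .tracking import (
    CONTESTED_MARK,
    KICK,
    MARK,
    SPOIL,
    TRACKING_COLUMNS,
    TRANSACTION_COLUMNS,
    FieldFormation,
    PlayerState,
    PlayerTrack,
    heading_angle,
    write_tracking,
    write_transactions,
)

__all__ = [
    "SimConfig",
    "SimConfigError",
    "SimResult",
    "commitment_rule",
    "simulate_match",
    "make_fixture",
    "Fixture",
    "FIXTURE_NAMES",
    "random_observations",
]

_DT = 0.1
_EPS = 1e-6

LEDGER_COLUMNS = [
    "contest_id", "t_p", "t_c", "contest_x", "contest_y", "contest_type",
    "player_id", "velocity", "time_to_point", "rel_x", "rel_y",
    "p_true", "committed",
]

PASS_LEDGER_COLUMNS = [
    "t_mark", "t_p", "t_c", "kicker_id", "receiver_id", "target_x", "target_y",
]


class SimConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic match process."""

    seed: int = 0
    n_plays: int = 60
    pass_fraction: float = 0.2       # fraction of plays that are mark->kick->mark
    players_per_team: int = 18
    field: FieldConfig = dc_field(default_factory=FieldConfig)
    frame_rate: float = 10.0
    ball_speed: float = 18.5

    # trajectory process (mean-reverting velocity toward roaming waypoints)
    reversion_rate: float = 2.2      # 1/s
    noise_scale: float = 2.0         # m/s per sqrt(s)
    speed_cap: float = 9.5           # m/s
    preferred_speed_min: float = 2.0
    preferred_speed_max: float = 9.0
    waypoint_interval: float = 4.0   # s
    waypoint_spread: float = 30.0    # m

    # ground-truth commitment rule
    commit_logit_base: float = 3.0   # logit at zero miss, 1 s flight, slow player
    commit_spread_x: float = 4.5     # m: lateral miss scale
    commit_spread_y: float = 2.0     # m: along-heading miss scale
    projection_gain: float = 0.9     # forward projection per (m/s * s)
    projection_horizon: float = 2.0  # s: cap on projected time
    time_penalty: float = 0.65       # logit drop per extra second of flight
    velocity_penalty: float = 0.12   # logit drop per m/s above 2 m/s
    commit_probability_scale: float = 1.0
    commit_radius: float = 2.0       # m: the labeling radius being emulated

    # play scheduling
    gap_min: int = 2                 # s between plays
    gap_max: int = 4
    contest_tt_weights: tuple = (0.3, 0.3, 0.2, 0.2)  # flight times 1..4 s

    def validate(self) -> None:
        if self.frame_rate != 10.0:
            raise SimConfigError("only 10 Hz simulation is supported")
        if self.players_per_team < 1:
            raise SimConfigError("players_per_team must be >= 1")
        for name in ("reversion_rate", "noise_scale", "ball_speed",
                     "commit_spread_x", "commit_spread_y", "waypoint_interval"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        if self.speed_cap < 9.0:
            raise SimConfigError("speed_cap must cover a typical sprint (>= 9 m/s)")
        if self.commit_radius >= min(self.field.semi_x, self.field.semi_y):
            raise SimConfigError("commit radius exceeds the field")
        if not 0.0 <= self.pass_fraction <= 1.0:
            raise SimConfigError("pass_fraction must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        field_cfg = raw.pop("field", None)
        if "contest_tt_weights" in raw:
            raw["contest_tt_weights"] = tuple(raw["contest_tt_weights"])
        cfg = cls(**raw)
        if field_cfg:
            cfg.field = FieldConfig(**field_cfg)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["contest_tt_weights"] = list(self.contest_tt_weights)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def commitment_rule(config: SimConfig, velocity, time_to_point, rel_x, rel_y):
    """Ground-truth commitment probability (vectorized).

    Logistic in the (elliptically scaled) distance from the contest to
    the player's velocity-projected point, penalized by flight time and
    speed.
    """
    v = np.asarray(velocity, dtype=float)
    t = np.asarray(time_to_point, dtype=float)
    rx = np.asarray(rel_x, dtype=float)
    ry = np.asarray(rel_y, dtype=float)
    proj = config.projection_gain * v * np.minimum(t, config.projection_horizon)
    miss = np.hypot(rx / config.commit_spread_x, (ry - proj) / config.commit_spread_y)
    logit = (
        config.commit_logit_base
        - miss
        - config.time_penalty * (t - 1.0)
        - config.velocity_penalty * np.maximum(v - 2.0, 0.0)
    )
    return config.commit_probability_scale * expit(logit)


def _smoothstep(u: float) -> float:
    return u * u * (3.0 - 2.0 * u)


class _Simulator:
    """Stateful 10 Hz match simulator; one instance per call, seeded once."""

    def __init__(self, config: SimConfig):
        config.validate()
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        ppt = config.players_per_team
        self.n = 2 * ppt
        self.ids = [f"a{i:02d}" for i in range(1, ppt + 1)] + [
            f"b{i:02d}" for i in range(1, ppt + 1)
        ]
        self.teams = ["team_a"] * ppt + ["team_b"] * ppt
        self.team_index = np.array([0] * ppt + [1] * ppt)

        self.anchors = self._sample_in_ellipse(self.n, 0.85)
        self.pos = self.anchors + self.rng.normal(0.0, 2.0, (self.n, 2))
        self.vel = np.zeros((self.n, 2))
        self.preferred = self.rng.uniform(
            config.preferred_speed_min, config.preferred_speed_max, self.n
        )
        self.waypoints = self.anchors.copy()
        self.wp_due = self.rng.uniform(0.0, config.waypoint_interval, self.n)
        self.last_dir = np.zeros(self.n)
        self.dir_defined = np.zeros(self.n, dtype=bool)

        self.k = 0
        self.frames: list[np.ndarray] = [self.pos.copy()]
        self.tx_rows: list[tuple] = []
        self.ledger_rows: list[tuple] = []
        self.pass_rows: list[tuple] = []
        self.contest_id = 0

    # -- geometry helpers --------------------------------------------------

    def _sample_in_ellipse(self, n: int, shrink: float) -> np.ndarray:
        r = np.sqrt(self.rng.uniform(0.0, 1.0, n))
        ang = self.rng.uniform(0.0, 2.0 * math.pi, n)
        f = self.cfg.field
        return np.column_stack(
            (f.semi_x * shrink * r * np.cos(ang), f.semi_y * shrink * r * np.sin(ang))
        )

    def _clamp_into(self, pts: np.ndarray, fraction: float) -> np.ndarray:
        f = self.cfg.field
        a = f.semi_x * fraction
        b = f.semi_y * fraction
        r = np.hypot(pts[:, 0] / a, pts[:, 1] / b)
        scale = np.where(r > 1.0, 1.0 / np.maximum(r, 1e-12), 1.0)
        return pts * scale[:, None]

    # -- core stepping -----------------------------------------------------

    def _step(self, overrides: dict[int, np.ndarray] | None = None) -> None:
        cfg = self.cfg
        t_now = self.k * _DT
        due = self.wp_due <= t_now
        m = int(due.sum())
        if m:
            fresh = self.anchors[due] + self.rng.normal(0.0, cfg.waypoint_spread, (m, 2))
            self.waypoints[due] = self._clamp_into(fresh, 0.9)
            self.wp_due[due] = t_now + cfg.waypoint_interval * (
                0.75 + 0.5 * self.rng.uniform(size=m)
            )
        to_wp = self.waypoints - self.pos
        dist = np.hypot(to_wp[:, 0], to_wp[:, 1])
        unit = to_wp / np.maximum(dist, 1e-9)[:, None]
        desired = self.preferred[:, None] * unit
        desired[dist < 2.0] = 0.0
        self.vel = (
            self.vel
            + cfg.reversion_rate * (desired - self.vel) * _DT
            + cfg.noise_scale * math.sqrt(_DT) * self.rng.standard_normal((self.n, 2))
        )
        speed = np.hypot(self.vel[:, 0], self.vel[:, 1])
        over = speed > cfg.speed_cap
        if over.any():
            self.vel[over] *= (cfg.speed_cap / speed[over])[:, None]
        new_pos = self.pos + self.vel * _DT
        outside = ~self.cfg.field.contains(new_pos[:, 0], new_pos[:, 1], margin=0.0)
        if np.any(outside):
            new_pos[outside] = self._clamp_into(new_pos[outside], 0.97)
            self.vel[outside] *= -0.5
            self.waypoints[outside] = 0.25 * self.anchors[outside]
            self.wp_due[outside] = t_now + self.cfg.waypoint_interval
        if overrides:
            for idx, p in overrides.items():
                new_pos[idx] = p
                self.vel[idx] = (p - self.pos[idx]) / _DT
        delta = new_pos - self.pos
        moved = np.hypot(delta[:, 0], delta[:, 1]) >= _EPS
        if moved.any():
            self.last_dir[moved] = np.arctan2(delta[moved, 0], delta[moved, 1]) % (
                2.0 * math.pi
            )
            self.dir_defined[moved] = True
        self.pos = new_pos
        self.frames.append(self.pos.copy())
        self.k += 1

    def _advance(self, n_steps: int) -> None:
        for _ in range(n_steps):
            self._step()

    def _segment_with_steering(
        self, n_steps: int, targets: dict[int, np.ndarray]
    ) -> None:
        starts = {idx: self.pos[idx].copy() for idx in targets}
        for s in range(1, n_steps + 1):
            frac = _smoothstep(s / n_steps)
            overrides = {
                idx: starts[idx] + frac * (tgt - starts[idx])
                for idx, tgt in targets.items()
            }
            self._step(overrides)

    def _repel(self, idx: int, target: np.ndarray, n_steps: int) -> None:
        """Push a non-committed player's segment endpoint outside the
        commitment radius, ramping the offset so the track stays smooth."""
        min_dist = 1.3 * self.cfg.commit_radius
        final = self.pos[idx]
        d = float(np.hypot(*(final - target)))
        if d >= min_dist:
            return
        if d > 1e-9:
            away = (final - target) / d
        else:
            away = np.array([0.0, 1.0])
        new_final = target + away * (min_dist + 0.8 * self.rng.uniform())
        if not self.cfg.field.contains(new_final[0], new_final[1], margin=0.0):
            norm_t = float(np.hypot(*target))
            inward = -target / norm_t if norm_t > 1e-9 else np.array([1.0, 0.0])
            new_final = target + inward * (min_dist + 0.8 * self.rng.uniform())
        offset = new_final - final
        for s in range(1, n_steps + 1):
            self.frames[self.k - n_steps + s][idx] += _smoothstep(s / n_steps) * offset
        self.pos[idx] = self.frames[self.k][idx].copy()
        delta = self.frames[self.k][idx] - self.frames[self.k - 1][idx]
        if float(np.hypot(*delta)) >= _EPS:
            self.last_dir[idx] = math.atan2(delta[0], delta[1]) % (2.0 * math.pi)
        self.vel[idx] = delta / _DT
        speed = float(np.hypot(*self.vel[idx]))
        if speed > self.cfg.speed_cap:
            self.vel[idx] *= self.cfg.speed_cap / speed

    # -- features ----------------------------------------------------------

    def _features(self):
        now = self.frames[self.k]
        prev = self.frames[self.k - 10]
        v = np.hypot(now[:, 0] - prev[:, 0], now[:, 1] - prev[:, 1])
        return now, v, self.last_dir.copy(), self.dir_defined.copy()

    # -- plays -------------------------------------------------------------

    def _choose_target(self, origin: np.ndarray, flight_times, weights):
        cfg = self.cfg
        for _ in range(60):
            dt_sec = int(self.rng.choice(flight_times, p=weights))
            ang = self.rng.uniform(0.0, 2.0 * math.pi)
            tgt = origin + cfg.ball_speed * dt_sec * np.array(
                [math.sin(ang), math.cos(ang)]
            )
            if cfg.field.contains(tgt[0], tgt[1], margin=-3.0):
                return tgt, dt_sec
        norm = float(np.hypot(*origin))
        inward = -origin / norm if norm > 1e-9 else np.array([0.0, 1.0])
        return origin + cfg.ball_speed * inward, 1

    def _contest_play(self) -> None:
        cfg = self.cfg
        t_p = self.k // 10
        kicker = int(self.rng.integers(self.n))
        kx, ky = self.pos[kicker]
        self.tx_rows.append((t_p, KICK, self.ids[kicker], float(kx), float(ky)))
        target, dt_sec = self._choose_target(
            self.pos[kicker], [1, 2, 3, 4], list(cfg.contest_tt_weights)
        )
        event_type = SPOIL if self.rng.random() < 0.5 else CONTESTED_MARK
        t_c = t_p + dt_sec

        now, v, dirs, defined = self._features()
        dvec = target[None, :] - now
        dist = np.hypot(dvec[:, 0], dvec[:, 1])
        committed: list[int] = []
        eligible: list[int] = []
        for idx in range(self.n):
            if dist[idx] > 35.0 or not defined[idx]:
                continue
            s_, c_ = math.sin(dirs[idx]), math.cos(dirs[idx])
            rel_x = dvec[idx, 0] * c_ - dvec[idx, 1] * s_
            rel_y = dvec[idx, 0] * s_ + dvec[idx, 1] * c_
            p = float(commitment_rule(cfg, v[idx], dt_sec, rel_x, rel_y))
            is_committed = bool(self.rng.random() < p)
            self.ledger_rows.append(
                (
                    self.contest_id, t_p, t_c, float(target[0]), float(target[1]),
                    event_type, self.ids[idx], float(v[idx]), float(dt_sec),
                    float(rel_x), float(rel_y), p, int(is_committed),
                )
            )
            eligible.append(idx)
            if is_committed:
                committed.append(idx)

        steer: dict[int, np.ndarray] = {}
        for idx in committed:
            r = 0.6 * cfg.commit_radius * math.sqrt(self.rng.uniform())
            ang = self.rng.uniform(0.0, 2.0 * math.pi)
            steer[idx] = target + r * np.array([math.sin(ang), math.cos(ang)])
        self._segment_with_steering(dt_sec * 10, steer)
        for idx in eligible:
            if idx not in steer:
                self._repel(idx, target, dt_sec * 10)

        if committed:
            contest_player = self.ids[committed[0]]
        else:
            contest_player = self.ids[int(np.argmin(dist))]
        self.tx_rows.append(
            (t_c, event_type, contest_player, float(target[0]), float(target[1]))
        )
        self.contest_id += 1

    def _pass_play(self) -> None:
        cfg = self.cfg
        t0 = self.k // 10
        kicker = int(self.rng.integers(self.n))
        self.tx_rows.append(
            (t0, MARK, self.ids[kicker], float(self.pos[kicker, 0]), float(self.pos[kicker, 1]))
        )
        self._advance(10)
        t_p = t0 + 1
        kx, ky = self.pos[kicker]
        self.tx_rows.append((t_p, KICK, self.ids[kicker], float(kx), float(ky)))
        target, dt_sec = self._choose_target(
            self.pos[kicker], [1, 2, 3], [0.4, 0.4, 0.2]
        )
        t_c = t_p + dt_sec
        teammates = [
            i for i in range(self.n)
            if i != kicker and self.team_index[i] == self.team_index[kicker]
        ]
        td = np.hypot(
            self.pos[teammates, 0] - target[0], self.pos[teammates, 1] - target[1]
        )
        receiver = teammates[int(np.argmin(td))]
        r = 0.5 * math.sqrt(self.rng.uniform())
        ang = self.rng.uniform(0.0, 2.0 * math.pi)
        self._segment_with_steering(
            dt_sec * 10,
            {receiver: target + r * np.array([math.sin(ang), math.cos(ang)])},
        )
        self.tx_rows.append(
            (t_c, MARK, self.ids[receiver], float(target[0]), float(target[1]))
        )
        self.pass_rows.append(
            (t0, t_p, t_c, self.ids[kicker], self.ids[receiver],
             float(target[0]), float(target[1]))
        )

    # -- entry point -------------------------------------------------------

    def run(self) -> "SimResult":
        cfg = self.cfg
        self._advance(30)  # warm-up so velocities exist 1 s before any event
        for _ in range(cfg.n_plays):
            if self.rng.random() < cfg.pass_fraction:
                self._pass_play()
            else:
                self._contest_play()
            gap = int(self.rng.integers(cfg.gap_min, cfg.gap_max + 1))
            self._advance(gap * 10)
        positions = np.stack(self.frames)  # (n_frames, n_players, 2)
        times = np.round(np.arange(positions.shape[0]) * _DT, 1)
        transactions = pd.DataFrame(self.tx_rows, columns=TRANSACTION_COLUMNS)
        transactions["timestamp"] = transactions["timestamp"].astype(np.int64)
        ledger = pd.DataFrame(self.ledger_rows, columns=LEDGER_COLUMNS)
        passes = pd.DataFrame(self.pass_rows, columns=PASS_LEDGER_COLUMNS)
        return SimResult(
            config=cfg,
            times=times,
            positions=positions,
            player_ids=list(self.ids),
            team_ids=list(self.teams),
            transactions=transactions,
            ledger=ledger,
            passes=passes,
        )


@dataclass
class SimResult:
    """Simulated match: raw trajectories, event stream, and ground truth."""

    config: SimConfig
    times: np.ndarray                # (n_frames,)
    positions: np.ndarray            # (n_frames, n_players, 2)
    player_ids: list[str]
    team_ids: list[str]
    transactions: pd.DataFrame
    ledger: pd.DataFrame             # one row per planted commitment draw
    passes: pd.DataFrame             # one row per planted mark->kick->mark

    @property
    def n_contests(self) -> int:
        if len(self.ledger) == 0:
            return 0
        return int(self.ledger["contest_id"].nunique())

    def tracking_frame(self) -> pd.DataFrame:
        """Full tracking stream as a tidy DataFrame (one row per frame/player)."""
        n_frames, n_players, _ = self.positions.shape
        return pd.DataFrame(
            {
                "timestamp": np.repeat(self.times, n_players),
                "player_id": np.tile(np.array(self.player_ids, dtype=object), n_frames),
                "team_id": np.tile(np.array(self.team_ids, dtype=object), n_frames),
                "x": self.positions[:, :, 0].ravel(),
                "y": self.positions[:, :, 1].ravel(),
            }
        )

    def tracks(self) -> dict[str, PlayerTrack]:
        """Per-player tracks built directly from the raw arrays."""
        out = {}
        for j, pid in enumerate(self.player_ids):
            out[pid] = PlayerTrack(
                pid,
                self.times,
                self.positions[:, j, 0],
                self.positions[:, j, 1],
                team_id=self.team_ids[j],
            )
        return out

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tracking(self.tracking_frame(), outdir / "tracking.csv")
        write_transactions(self.transactions, outdir / "transactions.csv")
        self.ledger.to_csv(outdir / "ledger.csv", index=False)
        self.passes.to_csv(outdir / "passes.csv", index=False)
        self.config.to_yaml(outdir / "sim_config.yaml")


def simulate_match(config: SimConfig | None = None) -> SimResult:
    """Run one seeded synthetic match (see module docstring)."""
    return _Simulator(config or SimConfig()).run()


# ---------------------------------------------------------------------------
# Plain random observation corpora (feature rows without a match behind them)
# ---------------------------------------------------------------------------

def random_observations(
    rng: np.random.Generator, n_committed: int, n_not_committed: int
) -> pd.DataFrame:
    """Plausible commitment training rows with exact class counts.

    Committed rows cluster near the player; non-committed rows spread over
    the 35 m inclusion disc.  Used where only the class bookkeeping (not a
    full match) matters.
    """
    def _rows(n, committed):
        v = rng.uniform(0.0, 8.0, n)
        t = rng.uniform(1.0, 4.0, n)
        if committed:
            rel_x = rng.normal(0.0, 2.0, n)
            rel_y = rng.normal(1.5, 2.5, n)
        else:
            radius = 35.0 * np.sqrt(rng.uniform(0.0, 1.0, n))
            ang = rng.uniform(0.0, 2.0 * math.pi, n)
            rel_x = radius * np.sin(ang)
            rel_y = radius * np.cos(ang)
        return pd.DataFrame(
            {
                "velocity": v,
                "time_to_point": t,
                "rel_x": rel_x,
                "rel_y": rel_y,
                "committed": int(committed),
            }
        )

    df = pd.concat([_rows(n_committed, True), _rows(n_not_committed, False)])
    return df.reset_index(drop=True)[OBSERVATION_COLUMNS]


# ---------------------------------------------------------------------------
# Deterministic miniature fixtures
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    """A small, fully deterministic dataset for unit tests."""

    name: str
    expected: dict
    tracking: pd.DataFrame | None = None
    transactions: pd.DataFrame | None = None
    formation: FieldFormation | None = None
    model: object = None
    equity: object = None
    field: FieldConfig = dc_field(default_factory=FieldConfig)
    kicker_id: str | None = None
    receiver_id: str | None = None
    receiver_location: tuple | None = None


def toy_commitment_model(seed: int = 42, bandwidth: float = 1.5):
    """Small deterministic fitted model: committed mass near the origin of
    the relative frame, non-committed mass in an annulus further out."""
    rng = np.random.default_rng(seed)
    committed = pd.DataFrame(
        {
            "velocity": rng.uniform(0.0, 4.0, 150),
            "time_to_point": rng.uniform(1.0, 3.0, 150),
            "rel_x": rng.normal(0.0, 1.5, 150),
            "rel_y": rng.normal(0.0, 1.5, 150),
            "committed": 1,
        }
    )
    radius = rng.uniform(6.0, 30.0, 450)
    ang = rng.uniform(0.0, 2.0 * math.pi, 450)
    not_committed = pd.DataFrame(
        {
            "velocity": rng.uniform(0.0, 8.0, 450),
            "time_to_point": rng.uniform(1.0, 4.0, 450),
            "rel_x": radius * np.sin(ang),
            "rel_y": radius * np.cos(ang),
            "committed": 0,
        }
    )
    obs = pd.concat([committed, not_committed]).reset_index(drop=True)
    return fit(obs, bandwidth=bandwidth)


def _linear_track(pid, team, start, velocity, t0=0.0, t1=15.0):
    ts = np.round(np.arange(t0, t1 + _DT / 2, _DT), 1)
    xs = start[0] + velocity[0] * (ts - t0)
    ys = start[1] + velocity[1] * (ts - t0)
    return pd.DataFrame(
        {"timestamp": ts, "player_id": pid, "team_id": team, "x": xs, "y": ys}
    )


def _fixture_two_player_contest() -> Fixture:
    tracking = pd.concat(
        [
            _linear_track("a01", "team_a", (0.0, -25.0), (0.0, 2.0)),
            _linear_track("b01", "team_b", (6.0, -5.0), (0.0, -1.5)),
        ]
    ).reset_index(drop=True)
    transactions = pd.DataFrame(
        [
            {"timestamp": 10, "event_type": KICK, "player_id": "a01", "x": 0.0, "y": -5.0},
            {"timestamp": 12, "event_type": SPOIL, "player_id": "b01", "x": 3.0, "y": -10.0},
        ]
    )[TRANSACTION_COLUMNS]
    return Fixture(
        name="two_player_contest",
        tracking=tracking,
        transactions=transactions,
        expected={"n_observations": 2, "n_contests": 1, "committed": [0, 0]},
    )


def _fixture_planted_optimum() -> Fixture:
    from .equity import SurrogateEquity

    field = FieldConfig()
    states = {
        "a_k": PlayerState("a_k", "team_a", 0.0, 0.0, 0.0, 0.0),
        "a_t": PlayerState("a_t", "team_a", 40.0, 0.0, 1.0, 0.0),
        "a_u": PlayerState("a_u", "team_a", -30.0, 0.0, 1.0, 0.0),
        "b_1": PlayerState("b_1", "team_b", -45.0, 25.0, 1.0, 0.0),
        "b_2": PlayerState("b_2", "team_b", -45.0, -25.0, 1.0, 0.0),
    }
    formation = FieldFormation(
        time=100.0, states=states, ball_position=(0.0, 0.0), attacking_team="team_a"
    )
    return Fixture(
        name="planted_optimum",
        formation=formation,
        model=toy_commitment_model(),
        equity=SurrogateEquity(field=field),
        field=field,
        kicker_id="a_k",
        receiver_id="a_t",
        receiver_location=(40.0, 0.0),
        expected={"alternative_id": "a_t", "dv": 1.0},
    )


def _fixture_symmetric_field() -> Fixture:
    half_pi = math.pi / 2.0
    states = {
        "a01": PlayerState("a01", "team_a", -20.0, 0.0, 2.0, half_pi),
        "a02": PlayerState("a02", "team_a", -35.0, 0.0, 2.0, half_pi),
        "b01": PlayerState("b01", "team_b", 20.0, 0.0, 2.0, 3.0 * half_pi),
        "b02": PlayerState("b02", "team_b", 35.0, 0.0, 2.0, 3.0 * half_pi),
    }
    formation = FieldFormation(
        time=0.0, states=states, ball_position=(0.0, 12.0), attacking_team="team_a"
    )
    return Fixture(
        name="symmetric_field",
        formation=formation,
        model=toy_commitment_model(),
        expected={"midpoint": (0.0, 0.0), "dominance": 0.5},
    )


_FIXTURES = {
    "two_player_contest": _fixture_two_player_contest,
    "planted_optimum": _fixture_planted_optimum,
    "symmetric_field": _fixture_symmetric_field,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def make_fixture(name: str) -> Fixture:
    """Build a registered miniature dataset (deterministic per name)."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder()
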