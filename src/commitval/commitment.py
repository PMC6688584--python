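"""Commitment modeling: contest extraction, the two-class 4-D kernel
density model, and commitment-probability (motion-model) surfaces.

A *contest* is a spoil or contested mark immediately preceded by a kick
whose location is inferable.  Every on-field player within 35 m of the
contest at pass time contributes one training observation with features
``(velocity, time_to_point, rel_x, rel_y)`` and a binary label: committed
(ended within 2 m of the contest at contest time) or not.

The fitted model is a pair of Gaussian kernel density estimators (one per
class, shared scalar bandwidth applied to all four raw dimensions, no
standardization) combined through the class-prior weight
``w = n_committed / n_total``::

    Pr(x) = w * f1(x) / (w * f1(x) + (1 - w) * f0(x))
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import KernelDensity

from .tracking import (
    CONTEST_EVENT_TYPES,
    KICK,
    ConsolidationResult,
    FieldFormation,
    PlayerTrack,
    to_relative,
)

__all__ = [
    "FEATURES",
    "DEFAULT_BANDWIDTH",
    "DEFAULT_COMMIT_RADIUS",
    "DEFAULT_MAX_DISTANCE",
    "FitError",
    "ContestEvent",
    "BuildCounts",
    "CommitmentModel",
    "MotionGrid",
    "extract_contests",
    "label_commitment",
    "build_observations",
    "fit",
    "commit_probability",
    "motion_model_grid",
    "save_model",
    "load_model",
]

FEATURES = ["velocity", "time_to_point", "rel_x", "rel_y"]
OBSERVATION_COLUMNS = FEATURES + ["committed"]

DEFAULT_BANDWIDTH = 1.5
DEFAULT_COMMIT_RADIUS = 2.0
DEFAULT_MAX_DISTANCE = 35.0

#: log-density floor below which both class densities are treated as zero
LOG_DENSITY_FLOOR = -690.0


class FitError(ValueError):
    """Raised when a commitment class has too few rows to fit a density."""


@dataclass(frozen=True)
class ContestEvent:
    """A qualifying contest and the field formation at its preceding pass."""

    index: int                       # row position in the transactions frame
    t_p: float                       # time of preceding kick (s)
    t_c: float                       # time of contest (s)
    location: tuple[float, float]    # inferred contest location (m)
    contest_type: str                # "spoil" or "contested_mark"
    kick_location: tuple[float, float]
    formation: FieldFormation        # formation at t_p

    @property
    def time_to_point(self) -> float:
        return self.t_c - self.t_p


def extract_contests(
    consolidated: ConsolidationResult,
) -> tuple[list[ContestEvent], list[int]]:
    """Find spoil / contested-mark transactions immediately preceded by a kick.

    Returns the contests plus the row positions of contest-type transactions
    that were skipped (no locatable preceding kick, or no formation at the
    kick's second).
    """
    tx = consolidated.transactions
    events = tx["event_type"].to_numpy()
    times = tx["timestamp"].to_numpy()
    contests: list[ContestEvent] = []
    skipped: list[int] = []
    for i in range(len(tx)):
        if events[i] not in CONTEST_EVENT_TYPES:
            continue
        j = i - 1
        if j < 0 or events[j] != KICK or j not in consolidated.formations:
            skipped.append(i)
            continue
        t_p = float(times[j])
        t_c = float(times[i])
        if t_c <= t_p:
            skipped.append(i)
            continue
        contests.append(
            ContestEvent(
                index=i,
                t_p=t_p,
                t_c=t_c,
                location=(float(tx["x"].iloc[i]), float(tx["y"].iloc[i])),
                contest_type=str(events[i]),
                kick_location=(float(tx["x"].iloc[j]), float(tx["y"].iloc[j])),
                formation=consolidated.formations[j],
            )
        )
    return contests, skipped


def label_commitment(
    contest_location, player_position_at_tc, radius: float = DEFAULT_COMMIT_RADIUS
) -> int:
    """1 iff the player ended within ``radius`` meters of the contest."""
    d = math.hypot(
        player_position_at_tc[0] - contest_location[0],
        player_position_at_tc[1] - contest_location[1],
    )
    return 1 if d <= radius else 0


@dataclass
class BuildCounts:
    """Bookkeeping for :func:`build_observations`."""

    n_contests: int = 0
    n_observations: int = 0
    outside_radius: int = 0
    undefined_kinematics: int = 0
    untracked_at_contest: int = 0


def build_observations(
    contests: Sequence[ContestEvent],
    tracks: Mapping[str, PlayerTrack],
    max_distance: float = DEFAULT_MAX_DISTANCE,
    commit_radius: float = DEFAULT_COMMIT_RADIUS,
) -> tuple[pd.DataFrame, BuildCounts]:
    """One training row per (contest, on-field player within ``max_distance``).

    Features are taken at the pass time ``t_p``; the label compares the
    player's tracked position at ``t_c`` against the contest location.
    Players with undefined velocity or direction at ``t_p``, or untracked at
    ``t_c``, are skipped and counted.
    """
    rows: list[tuple] = []
    counts = BuildCounts(n_contests=len(contests))
    for contest in contests:
        cx, cy = contest.location
        for pid, state in contest.formation.states.items():
            dist = math.hypot(state.x - cx, state.y - cy)
            if dist > max_distance:
                counts.outside_radius += 1
                continue
            if not (state.velocity_defined and state.direction_defined):
                counts.undefined_kinematics += 1
                continue
            pos_c = tracks[pid].position_at(contest.t_c) if pid in tracks else None
            if pos_c is None:
                counts.untracked_at_contest += 1
                continue
            rel_x, rel_y = to_relative(state, contest.location)
            rows.append(
                (
                    contest.index,
                    pid,
                    state.velocity,
                    contest.time_to_point,
                    rel_x,
                    rel_y,
                    label_commitment(contest.location, pos_c, commit_radius),
                )
            )
    counts.n_observations = len(rows)
    df = pd.DataFrame(
        rows, columns=["contest_index", "player_id"] + OBSERVATION_COLUMNS
    )
    return df, counts


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class CommitmentModel:
    """Fitted pair of 4-D class densities plus the prior weight ``w``."""

    bandwidth: float
    w: float
    n_committed: int
    n_not_committed: int
    training: pd.DataFrame = dc_field(repr=False)
    kde_committed: KernelDensity = dc_field(repr=False, default=None)
    kde_not_committed: KernelDensity = dc_field(repr=False, default=None)

    @property
    def n_total(self) -> int:
        return self.n_committed + self.n_not_committed

    def log_class_densities(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Log of ``f1`` and ``f0`` at query rows ``X`` (shape (m, 4))."""
        return (
            self.kde_committed.score_samples(X),
            self.kde_not_committed.score_samples(X),
        )


def fit(
    observations: pd.DataFrame,
    bandwidth: float = DEFAULT_BANDWIDTH,
    rtol: float = 1e-9,
) -> CommitmentModel:
    """Fit the two class densities on raw (unstandardized) features.

    Requires at least 2 rows per class.  The fit is deterministic given the
    rows: ``w`` is the committed fraction of the training set.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    X = observations[FEATURES].to_numpy(dtype=float)
    c = observations["committed"].to_numpy()
    X1 = X[c == 1]
    X0 = X[c == 0]
    if len(X1) < 2 or len(X0) < 2:
        raise FitError(
            f"need >= 2 rows per class to fit, got committed={len(X1)} "
            f"not_committed={len(X0)}; supply a larger corpus"
        )
    kde1 = KernelDensity(bandwidth=bandwidth, kernel="gaussian", rtol=rtol).fit(X1)
    kde0 = KernelDensity(bandwidth=bandwidth, kernel="gaussian", rtol=rtol).fit(X0)
    return CommitmentModel(
        bandwidth=bandwidth,
        w=len(X1) / (len(X1) + len(X0)),
        n_committed=len(X1),
        n_not_committed=len(X0),
        training=observations[OBSERVATION_COLUMNS].reset_index(drop=True),
        kde_committed=kde1,
        kde_not_committed=kde0,
    )


def commit_probability(
    model: CommitmentModel,
    velocity,
    time_to_point,
    rel_x,
    rel_y,
    return_flags: bool = False,
):
    """Evaluate ``Pr = w f1 / (w f1 + (1 - w) f0)``; broadcasts over inputs.

    Far from all training data both densities underflow; such points get
    probability 0 and, with ``return_flags=True``, a True underflow flag.
    """
    v, t, rx, ry = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (velocity, time_to_point, rel_x, rel_y))
    )
    shape = v.shape
    X = np.column_stack([a.reshape(-1) for a in (v, t, rx, ry)])
    log_f1, log_f0 = model.log_class_densities(X)
    l1 = log_f1 + math.log(model.w)
    l0 = log_f0 + math.log1p(-model.w)
    underflow = np.maximum(l1, l0) < LOG_DENSITY_FLOOR
    with np.errstate(invalid="ignore", over="ignore"):
        delta = l0 - l1
        pr = np.where(
            np.isneginf(l1) & np.isneginf(l0),
            0.0,
            1.0 / (1.0 + np.exp(delta)),
        )
    pr = np.where(underflow, 0.0, pr)
    pr = pr.reshape(shape)
    underflow = underflow.reshape(shape)
    if shape == ():
        pr = float(pr)
        underflow = bool(underflow)
    if return_flags:
        return pr, underflow
    return pr


@dataclass
class MotionGrid:
    """Commitment-probability surface over relative coordinates."""

    rel_x: np.ndarray            # 1-D axis
    rel_y: np.ndarray            # 1-D axis
    values: np.ndarray           # shape (len(rel_x), len(rel_y))
    velocity: float
    time_to_point: float
    peak_location: tuple[float, float]
    peak_value: float

    def to_frame(self) -> pd.DataFrame:
        rx, ry = np.meshgrid(self.rel_x, self.rel_y, indexing="ij")
        return pd.DataFrame(
            {
                "rel_x": rx.ravel(),
                "rel_y": ry.ravel(),
                "probability": self.values.ravel(),
            }
        )


def motion_model_grid(
    model: CommitmentModel,
    velocity: float,
    time_to_point: float,
    extent: float = 35.0,
    step: float = 1.0,
) -> MotionGrid:
    """Sample the commitment probability over ``(rel_x, rel_y)`` cell centers.

    Cells sit at integer multiples of ``step`` spanning ``[-extent, extent]``
    in both axes; the returned grid also carries the argmax cell and value.
    """
    axis = np.arange(-extent, extent + step / 2.0, step)
    rx, ry = np.meshgrid(axis, axis, indexing="ij")
    values = commit_probability(model, velocity, time_to_point, rx, ry)
    flat_peak = int(np.argmax(values))
    ix, iy = np.unravel_index(flat_peak, values.shape)
    return MotionGrid(
        rel_x=axis,
        rel_y=axis,
        values=values,
        velocity=float(velocity),
        time_to_point=float(time_to_point),
        peak_location=(float(axis[ix]), float(axis[iy])),
        peak_value=float(values[ix, iy]),
    )


# ---------------------------------------------------------------------------
# Model archive
# ---------------------------------------------------------------------------

_ARCHIVE_VERSION = 1


def save_model(model: CommitmentModel, directory) -> None:
    """Persist training rows + metadata; enough to refit deterministically."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model.training.to_csv(directory / "observations.csv", index=False)
    meta = {
        "version": _ARCHIVE_VERSION,
        "kernel": "gaussian",
        "bandwidth": model.bandwidth,
        "w": model.w,
        "n_committed": model.n_committed,
        "n_not_committed": model.n_not_committed,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_model(directory) -> CommitmentModel:
    """Refit a model from an archive written by :func:`save_model`."""
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    observations = pd.read_csv(directory / "observations.csv")
    model = fit(observations, bandwidth=float(meta["bandwidth"]))
    if abs(model.w - float(meta["w"])) > 1e-9:
        raise FitError(
            f"archive inconsistent: stored w={meta['w']} but refit gives {model.w}"
        )
    return model
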