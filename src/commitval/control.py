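"""Team spatial control: influence, dominance, and pass-outcome
probabilities on a regular grid.

A team's influence at a cell is the sum of its players' commitment
probabilities, each evaluated with the ball's time-to-point to that cell
(straight-line flight at constant speed).  Dominance is the attacking
share of total influence, and the mark probability ("risk" of a pass;
higher = safer) is dominance times influence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd

from .commitment import CommitmentModel, commit_probability
from .field import FieldConfig
from .tracking import FieldFormation, FormationError, PlayerState

__all__ = [
    "DEFAULT_BALL_SPEED",
    "DEFAULT_INFLUENCE_RADIUS",
    "GridSpec",
    "ControlSurface",
    "player_probability_field",
    "team_influence",
    "dominance",
    "mark_probability",
    "outcome_probabilities",
    "surface_to_frame",
]

#: constant straight-line ball flight speed (m/s)
DEFAULT_BALL_SPEED = 18.5

#: commitment probability is treated as zero beyond this distance from the
#: player (training rows only exist within 35 m; the Gaussian tail at 45 m
#: with bandwidth 1.5 is < 1e-9)
DEFAULT_INFLUENCE_RADIUS = 45.0


@dataclass(frozen=True)
class GridSpec:
    """Regular grid of cell centers; arrays are indexed ``[ix, iy]``."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    step: float = 1.0

    @classmethod
    def centered(cls, extent: float, step: float = 1.0) -> "GridSpec":
        return cls(-extent, extent, -extent, extent, step)

    @classmethod
    def for_field(cls, field: FieldConfig, step: float = 1.0) -> "GridSpec":
        """Integer-meter cells covering the field's bounding box."""
        sx = math.ceil(field.semi_x)
        sy = math.ceil(field.semi_y)
        return cls(-sx, sx, -sy, sy, step)

    @cached_property
    def xs(self) -> np.ndarray:
        return np.arange(self.x_min, self.x_max + self.step / 2.0, self.step)

    @cached_property
    def ys(self) -> np.ndarray:
        return np.arange(self.y_min, self.y_max + self.step / 2.0, self.step)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.xs), len(self.ys))

    def cells(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.xs, self.ys, indexing="ij")

    def nearest_index(self, x: float, y: float) -> tuple[int, int]:
        ix = int(round((x - self.x_min) / self.step))
        iy = int(round((y - self.y_min) / self.step))
        return (
            min(max(ix, 0), len(self.xs) - 1),
            min(max(iy, 0), len(self.ys) - 1),
        )


def player_probability_field(
    model: CommitmentModel,
    state: PlayerState,
    ball_origin,
    grid: GridSpec,
    ball_speed: float = DEFAULT_BALL_SPEED,
    influence_radius: float = DEFAULT_INFLUENCE_RADIUS,
) -> np.ndarray:
    """One player's commitment probability at every grid cell.

    Each cell's time-to-point is its distance from the ball origin divided
    by the ball speed.  Players with undefined kinematics are treated as
    stationary and isotropic (velocity 0, direction 0).
    """
    X, Y = grid.cells()
    dx = X - state.x
    dy = Y - state.y
    player_dist = np.hypot(dx, dy)
    near = player_dist <= influence_radius
    out = np.zeros(grid.shape)
    if not np.any(near):
        return out
    ttp = np.hypot(X - ball_origin[0], Y - ball_origin[1]) / ball_speed
    theta = state.direction if state.direction_defined else 0.0
    s, c = math.sin(theta), math.cos(theta)
    rel_x = dx * c - dy * s
    rel_y = dx * s + dy * c
    v = state.velocity if state.velocity_defined else 0.0
    out[near] = commit_probability(model, v, ttp[near], rel_x[near], rel_y[near])
    return out


def team_influence(
    model: CommitmentModel,
    formation: FieldFormation,
    team_id: str,
    ball_origin,
    grid: GridSpec,
    ball_speed: float = DEFAULT_BALL_SPEED,
    influence_radius: float = DEFAULT_INFLUENCE_RADIUS,
    expected_players: int | None = None,
) -> np.ndarray:
    """Summed commitment probabilities of a team's on-field players (INF)."""
    states = formation.team_states(team_id)
    if expected_players is not None and len(states) != expected_players:
        raise FormationError(
            f"team {team_id!r} has {len(states)} players, expected {expected_players}"
        )
    out = np.zeros(grid.shape)
    for state in states:
        out += player_probability_field(
            model, state, ball_origin, grid,
            ball_speed=ball_speed, influence_radius=influence_radius,
        )
    return out


def dominance(inf_a, inf_o, neutral: float = 0.5):
    """Attacking share of total influence; cells with no influence from
    either team get the ``neutral`` value (0.5 by default)."""
    inf_a = np.asarray(inf_a, dtype=float)
    inf_o = np.asarray(inf_o, dtype=float)
    total = inf_a + inf_o
    safe = np.where(total > 0.0, total, 1.0)
    return np.where(total > 0.0, inf_a / safe, neutral)


def mark_probability(dom, inf):
    """Probability of a pass to a cell producing a mark: DOM * INF."""
    return np.asarray(dom, dtype=float) * np.asarray(inf, dtype=float)


@dataclass
class ControlSurface:
    """All control quantities for one formation / ball origin on one grid."""

    grid: GridSpec
    attacking_team: str
    ball_origin: tuple[float, float]
    influence_attacking: np.ndarray
    influence_opponent: np.ndarray
    dominance_attacking: np.ndarray
    mark_prob_attacking: np.ndarray
    mark_prob_opponent: np.ndarray

    @classmethod
    def compute(
        cls,
        model: CommitmentModel,
        formation: FieldFormation,
        attacking_team: str,
        ball_origin,
        grid: GridSpec,
        ball_speed: float = DEFAULT_BALL_SPEED,
        influence_radius: float = DEFAULT_INFLUENCE_RADIUS,
        expected_players: int | None = None,
    ) -> "ControlSurface":
        opponent = formation.opponent_of(attacking_team)
        inf_a = team_influence(
            model, formation, attacking_team, ball_origin, grid,
            ball_speed=ball_speed, influence_radius=influence_radius,
            expected_players=expected_players,
        )
        inf_o = team_influence(
            model, formation, opponent, ball_origin, grid,
            ball_speed=ball_speed, influence_radius=influence_radius,
            expected_players=expected_players,
        )
        dom_a = dominance(inf_a, inf_o)
        return cls(
            grid=grid,
            attacking_team=attacking_team,
            ball_origin=(float(ball_origin[0]), float(ball_origin[1])),
            influence_attacking=inf_a,
            influence_opponent=inf_o,
            dominance_attacking=dom_a,
            mark_prob_attacking=mark_probability(dom_a, inf_a),
            mark_prob_opponent=mark_probability(1.0 - dom_a, inf_o),
        )


def outcome_probabilities(
    surface: ControlSurface,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell ``(p_A, p_B, p_C, p_D)``.

    Mark outcomes use dominance times influence; post-bounce outcomes are
    the dominances themselves.  The four values are used exactly as defined
    and are not renormalized (they need not sum to 1).
    """
    p_a = surface.mark_prob_attacking
    p_c = surface.mark_prob_opponent
    p_b = surface.dominance_attacking
    p_d = 1.0 - surface.dominance_attacking
    return p_a, p_b, p_c, p_d


def surface_to_frame(surface: ControlSurface) -> pd.DataFrame:
    """Flatten a control surface to ``x,y,inf_a,inf_o,dom_a,p_a,p_b,p_c,p_d``."""
    X, Y = surface.grid.cells()
    p_a, p_b, p_c, p_d = outcome_probabilities(surface)
    return pd.DataFrame(
        {
            "x": X.ravel(),
            "y": Y.ravel(),
            "inf_a": surface.influence_attacking.ravel(),
            "inf_o": surface.influence_opponent.ravel(),
            "dom_a": surface.dominance_attacking.ravel(),
            "p_a": p_a.ravel(),
            "p_b": p_b.ravel(),
            "p_c": p_c.ravel(),
            "p_d": p_d.ravel(),
        }
    )
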