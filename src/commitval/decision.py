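"""Pass decision valuation: expected outcome surfaces, kicking-variance
smoothing, optimal-alternative search, and decision value.

The expected outcome (EO) of kicking to a cell combines the four pass
outcomes with the field equity of each team::

    EO = (p_A + p_B) * e_a - (p_C + p_D) * e_o

Raw EO is smoothed with a truncated isotropic Gaussian whose standard
deviation (and truncation radius) is 5% of the kicking distance, weights
renormalized over the truncation set so a constant field is a fixed
point.  The decision value of an executed pass is its smoothed EO divided
by the best smoothed EO among teammates within the 60 m kicking radius,
clamped below at -1; when that optimum is non-positive the ratio is
ill-behaved and the DV is flagged undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .commitment import CommitmentModel
from .control import (
    DEFAULT_BALL_SPEED,
    DEFAULT_INFLUENCE_RADIUS,
    ControlSurface,
    GridSpec,
    outcome_probabilities,
)
from .field import FieldConfig
from .tracking import (
    KICK,
    MARK,
    ConsolidationResult,
    FieldFormation,
    build_tracks,
    consolidate,
)

__all__ = [
    "DEFAULT_KICK_RADIUS",
    "DEFAULT_SPREAD_FRACTION",
    "EOSurface",
    "Alternative",
    "OptionMetrics",
    "PassEvaluation",
    "expected_outcome",
    "kick_smoothing",
    "decision_value",
    "find_alternative",
    "evaluate_pass",
    "evaluate_passes",
    "EVALUATION_COLUMNS",
]

#: maximum kicking range (m): options beyond this distance are not considered
DEFAULT_KICK_RADIUS = 60.0

#: kick scatter: Gaussian sigma and truncation radius as a fraction of
#: kicking distance
DEFAULT_SPREAD_FRACTION = 0.05


@dataclass
class EOSurface:
    """Raw and smoothed expected-outcome values on a grid.

    ``valid`` marks cells inside the field; ``in_range`` marks cells within
    the kicking radius of the kicker.
    """

    grid: GridSpec
    raw: np.ndarray
    smoothed: np.ndarray
    kicker_location: tuple[float, float]
    valid: np.ndarray
    in_range: np.ndarray


def expected_outcome(
    surface: ControlSurface,
    equity_model,
    attacking_direction: int = 1,
) -> np.ndarray:
    """Raw EO at every cell: ``(p_A + p_B) e_a - (p_C + p_D) e_o``."""
    X, Y = surface.grid.cells()
    e_a = np.asarray(equity_model.evaluate(X, Y, attacking_direction), dtype=float)
    e_o = np.asarray(equity_model.evaluate(X, Y, -attacking_direction), dtype=float)
    p_a, p_b, p_c, p_d = outcome_probabilities(surface)
    return (p_a + p_b) * e_a - (p_c + p_d) * e_o


def _offset_cache(max_cells: int, step: float):
    offsets = {}
    for m in range(1, max_cells + 1):
        rng = np.arange(-m, m + 1)
        ox, oy = np.meshgrid(rng, rng, indexing="ij")
        ox = ox.ravel()
        oy = oy.ravel()
        d2 = (ox * step) ** 2 + (oy * step) ** 2
        offsets[m] = (ox, oy, d2)
    return offsets


def kick_smoothing(
    raw: np.ndarray,
    grid: GridSpec,
    kicker_location,
    valid: np.ndarray | None = None,
    spread_fraction: float = DEFAULT_SPREAD_FRACTION,
) -> np.ndarray:
    """Smooth raw EO with a distance-dependent truncated Gaussian.

    For each cell the scatter radius is ``spread_fraction`` times the
    kicking distance; cells whose radius is below one grid step keep their
    raw value.  Weights are a Gaussian with sigma equal to the radius,
    truncated at the radius, restricted to valid in-grid cells, and
    renormalized to sum to 1.
    """
    kx, ky = kicker_location
    X, Y = grid.cells()
    dist = np.hypot(X - kx, Y - ky)
    radius = spread_fraction * dist
    if valid is None:
        valid = np.ones(grid.shape, dtype=bool)
    out = raw.copy()
    needs = (radius >= grid.step) & valid
    if not np.any(needs):
        return out
    max_cells = int(math.floor(float(radius.max()) / grid.step))
    cache = _offset_cache(max_cells, grid.step)
    nx, ny = grid.shape
    for ix, iy in np.argwhere(needs):
        r = radius[ix, iy]
        ox, oy, d2 = cache[int(math.floor(r / grid.step))]
        jx = ix + ox
        jy = iy + oy
        keep = (d2 <= r * r) & (jx >= 0) & (jx < nx) & (jy >= 0) & (jy < ny)
        jx = jx[keep]
        jy = jy[keep]
        keep_valid = valid[jx, jy]
        jx = jx[keep_valid]
        jy = jy[keep_valid]
        w = np.exp(-d2[keep][keep_valid] / (2.0 * r * r))
        w /= w.sum()
        out[ix, iy] = float(np.dot(w, raw[jx, jy]))
    return out


def decision_value(eo: float, eo_opt: float) -> tuple[float, bool]:
    """``(DV, defined)``: EO over the best EO in range, clamped below at -1.

    When ``eo_opt`` is non-positive the ratio flips sign and is meaningless;
    such events return ``(nan, False)`` and are excluded from DV summaries.
    """
    if eo_opt <= 0.0:
        return (float("nan"), False)
    return (max(eo / eo_opt, -1.0), True)


@dataclass(frozen=True)
class Alternative:
    player_id: str
    location: tuple[float, float]
    eo: float


def find_alternative(
    surface: EOSurface,
    formation: FieldFormation,
    kicker_id: str,
    kick_radius: float = DEFAULT_KICK_RADIUS,
) -> Alternative | None:
    """Best smoothed EO among on-field teammates within the kicking radius.

    Deterministic: ties are broken by lowest player id.  Returns None when
    no teammate is in range.
    """
    kicker = formation.states[kicker_id]
    best: Alternative | None = None
    for pid in sorted(formation.states):
        if pid == kicker_id:
            continue
        state = formation.states[pid]
        if state.team_id != kicker.team_id:
            continue
        if math.hypot(state.x - kicker.x, state.y - kicker.y) > kick_radius:
            continue
        ix, iy = surface.grid.nearest_index(state.x, state.y)
        eo = float(surface.smoothed[ix, iy])
        if best is None or eo > best.eo:
            best = Alternative(player_id=pid, location=state.position, eo=eo)
    return best


@dataclass(frozen=True)
class OptionMetrics:
    """Control and value metrics of one pass option, read at its grid cell."""

    player_id: str | None
    location: tuple[float, float]
    dominance: float
    influence: float
    risk: float
    eo: float
    distance: float


@dataclass
class PassEvaluation:
    """One analyzed pass: the executed decision and its best alternative."""

    kicker_id: str
    kicker_team: str
    receiver_id: str | None
    t_p: float
    decision: OptionMetrics
    alternative: OptionMetrics | None
    dv: float
    dv_defined: bool
    surface: EOSurface | None = None


def _option_metrics(
    control: ControlSurface,
    eo_surface: EOSurface,
    kicker_location,
    location,
    player_id=None,
) -> OptionMetrics:
    ix, iy = control.grid.nearest_index(location[0], location[1])
    return OptionMetrics(
        player_id=player_id,
        location=(float(location[0]), float(location[1])),
        dominance=float(control.dominance_attacking[ix, iy]),
        influence=float(control.influence_attacking[ix, iy]),
        risk=float(control.mark_prob_attacking[ix, iy]),
        eo=float(eo_surface.smoothed[ix, iy]),
        distance=math.hypot(
            location[0] - kicker_location[0], location[1] - kicker_location[1]
        ),
    )


def evaluate_pass(
    formation: FieldFormation,
    kicker_id: str,
    receiver_location,
    model: CommitmentModel,
    equity_model,
    receiver_id: str | None = None,
    field: FieldConfig | None = None,
    grid: GridSpec | None = None,
    ball_speed: float = DEFAULT_BALL_SPEED,
    kick_radius: float = DEFAULT_KICK_RADIUS,
    influence_radius: float = DEFAULT_INFLUENCE_RADIUS,
    attacking_direction: int = 1,
    keep_surface: bool = False,
) -> PassEvaluation:
    """Score one executed pass against the best available alternative.

    Builds the control and EO surfaces from the formation frozen at pass
    time with the ball at the kicker, reads the decision's metrics at the
    receiver's location, finds the optimal teammate option, and computes
    the decision value.
    """
    field = field or FieldConfig()
    grid = grid or GridSpec.for_field(field)
    kicker = formation.states[kicker_id]
    control = ControlSurface.compute(
        model, formation, kicker.team_id, kicker.position, grid,
        ball_speed=ball_speed, influence_radius=influence_radius,
    )
    raw = expected_outcome(control, equity_model, attacking_direction)
    X, Y = grid.cells()
    valid = field.contains(X, Y, margin=0.0)
    smoothed = kick_smoothing(raw, grid, kicker.position, valid=valid)
    in_range = np.hypot(X - kicker.x, Y - kicker.y) <= kick_radius
    eo_surface = EOSurface(
        grid=grid, raw=raw, smoothed=smoothed,
        kicker_location=kicker.position, valid=valid, in_range=in_range,
    )
    decision = _option_metrics(
        control, eo_surface, kicker.position, receiver_location, receiver_id
    )
    alt = find_alternative(eo_surface, formation, kicker_id, kick_radius)
    alt_metrics = None
    dv, dv_defined = float("nan"), False
    if alt is not None:
        alt_metrics = _option_metrics(
            control, eo_surface, kicker.position, alt.location, alt.player_id
        )
        # the executed pass is itself an in-range option: when its EO (read
        # at the receiver's mark location) beats every teammate's pass-time
        # cell, the decision was optimal and DV = 1
        dv, dv_defined = decision_value(decision.eo, max(alt.eo, decision.eo))
    return PassEvaluation(
        kicker_id=kicker_id,
        kicker_team=kicker.team_id,
        receiver_id=receiver_id,
        t_p=formation.time,
        decision=decision,
        alternative=alt_metrics,
        dv=dv,
        dv_defined=dv_defined,
        surface=eo_surface if keep_surface else None,
    )


EVALUATION_COLUMNS = [
    "match_id",
    "t_p",
    "kicker_id",
    "kicker_team",
    "receiver_id",
    "alt_id",
    "dom_dec",
    "inf_dec",
    "risk_dec",
    "eo_dec",
    "dist_dec",
    "dom_alt",
    "inf_alt",
    "risk_alt",
    "eo_alt",
    "dist_alt",
    "dv",
    "dv_defined",
]


@dataclass
class EvaluationDiagnostics:
    n_kicks: int = 0
    n_evaluated: int = 0
    no_preceding_mark: int = 0
    next_not_mark: int = 0
    receiver_not_teammate: int = 0
    no_formation: int = 0
    no_alternative: int = 0


def evaluate_passes(
    tracking: pd.DataFrame,
    transactions: pd.DataFrame,
    model: CommitmentModel,
    equity_model,
    field: FieldConfig | None = None,
    match_id: str = "match",
    ball_speed: float = DEFAULT_BALL_SPEED,
    kick_radius: float = DEFAULT_KICK_RADIUS,
    influence_radius: float = DEFAULT_INFLUENCE_RADIUS,
    consolidated: ConsolidationResult | None = None,
) -> tuple[pd.DataFrame, EvaluationDiagnostics]:
    """Evaluate every mark -> kick -> mark chain in a match.

    Only kicks taken from a mark are decisions; the destination is only
    locatable when the next possession is itself a mark, and the receiving
    mark must be by a teammate (an intercepted ball has no intended-target
    location).  Skipped kicks are tallied in the diagnostics.
    """
    field = field or FieldConfig()
    if consolidated is None:
        consolidated = consolidate(tracking, transactions)
    tx = consolidated.transactions
    events = tx["event_type"].to_numpy()
    players = tx["player_id"].astype(str).to_numpy()
    tracks = build_tracks(tracking)
    team_of = {pid: tr.team_id for pid, tr in tracks.items()}
    grid = GridSpec.for_field(field)

    diag = EvaluationDiagnostics()
    rows = []
    for i in range(len(tx)):
        if events[i] != KICK:
            continue
        diag.n_kicks += 1
        if i == 0 or events[i - 1] != MARK or players[i - 1] != players[i]:
            diag.no_preceding_mark += 1
            continue
        if i + 1 >= len(tx) or events[i + 1] != MARK:
            diag.next_not_mark += 1
            continue
        kicker_id = players[i]
        receiver_id = players[i + 1]
        if team_of.get(receiver_id) != team_of.get(kicker_id):
            diag.receiver_not_teammate += 1
            continue
        if i not in consolidated.formations:
            diag.no_formation += 1
            continue
        formation = consolidated.formations[i]
        receiver_location = (float(tx["x"].iloc[i + 1]), float(tx["y"].iloc[i + 1]))
        ev = evaluate_pass(
            formation, kicker_id, receiver_location, model, equity_model,
            receiver_id=receiver_id, field=field, grid=grid,
            ball_speed=ball_speed, kick_radius=kick_radius,
            influence_radius=influence_radius,
        )
        if ev.alternative is None:
            diag.no_alternative += 1
            continue
        diag.n_evaluated += 1
        rows.append(
            (
                match_id,
                ev.t_p,
                ev.kicker_id,
                ev.kicker_team,
                ev.receiver_id,
                ev.alternative.player_id,
                ev.decision.dominance,
                ev.decision.influence,
                ev.decision.risk,
                ev.decision.eo,
                ev.decision.distance,
                ev.alternative.dominance,
                ev.alternative.influence,
                ev.alternative.risk,
                ev.alternative.eo,
                ev.alternative.distance,
                ev.dv,
                ev.dv_defined,
            )
        )
    return pd.DataFrame(rows, columns=EVALUATION_COLUMNS), diag
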