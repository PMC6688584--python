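"""Field equity providers: the reward term of the decision model.

Equity is the expected scoring value (points) of possession at a field
location for a given attacking direction.  Two providers are available:

* :class:`SurrogateEquity` — a parametric stand-in: the difference of two
  exponential goal-proximity terms, each decaying with distance to a goal
  and with the absolute angle off the goal axis, scaled to +/- the value
  of a goal.  It is antisymmetric: the defending team's equity at a
  location is the negative of the attacker's, and equity deep in defense
  is negative.
* :class:`LookupEquity` — a gridded table (``x,y,equity_attacking_right``)
  for substituting an externally derived equity surface; the
  attacking-left value is the x-mirrored lookup.

All decision-model code depends only on the ``evaluate(x, y, direction)``
interface, so providers are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .field import FieldConfig

__all__ = [
    "EquityDomainError",
    "EquityTableError",
    "SurrogateEquity",
    "LookupEquity",
    "load_equity_table",
    "write_equity_table",
]


class EquityDomainError(ValueError):
    """Scalar equity query outside the field bounds."""


class EquityTableError(ValueError):
    """An equity table does not cover the required field cells."""


@dataclass(frozen=True)
class SurrogateEquity:
    """Antisymmetric parametric equity surrogate.

    ``evaluate`` computes ``V * (g_att - g_def)`` where each ``g`` is
    ``exp(-d / decay_length) * ((1 + cos(theta)) / 2) ** angle_weight``
    for the distance ``d`` and off-axis angle ``theta`` to the respective
    goal.  ``g`` is monotone decreasing in both ``d`` and ``|theta|``.
    """

    field: FieldConfig = dc_field(default_factory=FieldConfig)
    max_value: float = 6.0
    decay_length: float = 40.0
    angle_weight: float = 1.0

    def _goal_term(self, x, y, goal_direction: int):
        gx, gy = self.field.goal_center(goal_direction)
        ux = gx - x
        uy = gy - y
        dist = np.hypot(ux, uy)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_theta = np.where(dist > 0.0, goal_direction * ux / np.where(dist > 0, dist, 1.0), 1.0)
        angle_term = ((1.0 + cos_theta) / 2.0) ** self.angle_weight
        return np.exp(-dist / self.decay_length) * angle_term

    def evaluate(self, x, y, direction: int = 1):
        """Equity at (x, y) for a team attacking toward ``direction`` (+1/-1).

        Pure formula, vectorized, no bounds check (use :meth:`equity` for
        the checked scalar form).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        g_att = self._goal_term(x, y, direction)
        g_def = self._goal_term(x, y, -direction)
        out = self.max_value * (g_att - g_def)
        if out.ndim == 0:
            return float(out)
        return out

    def equity(self, x: float, y: float, direction: int = 1) -> float:
        if not self.field.contains(x, y):
            raise EquityDomainError(f"location ({x}, {y}) is outside the field")
        return float(self.evaluate(x, y, direction))


@dataclass
class LookupEquity:
    """Nearest-cell lookup over a regular equity table.

    The stored values are for a team attacking toward +x; the attacking
    -x value at (x, y) is the stored value at (-x, y).
    """

    x_min: float
    y_min: float
    step: float
    values: np.ndarray          # shape (nx, ny), NaN where absent
    field: FieldConfig = dc_field(default_factory=FieldConfig)

    def _lookup(self, x, y):
        ix = np.rint((np.asarray(x, dtype=float) - self.x_min) / self.step).astype(int)
        iy = np.rint((np.asarray(y, dtype=float) - self.y_min) / self.step).astype(int)
        ix = np.clip(ix, 0, self.values.shape[0] - 1)
        iy = np.clip(iy, 0, self.values.shape[1] - 1)
        return self.values[ix, iy]

    def evaluate(self, x, y, direction: int = 1):
        """Vectorized nearest-cell lookup; cells absent from the table are 0."""
        if direction == -1:
            x = -np.asarray(x, dtype=float)
        out = np.nan_to_num(self._lookup(x, y), nan=0.0)
        if np.ndim(out) == 0:
            return float(out)
        return out

    def equity(self, x: float, y: float, direction: int = 1) -> float:
        if not self.field.contains(x, y):
            raise EquityDomainError(f"location ({x}, {y}) is outside the field")
        qx = -x if direction == -1 else x
        v = float(self._lookup(qx, y))
        if np.isnan(v):
            raise EquityTableError(f"no table entry near ({qx}, {y})")
        return v


EQUITY_TABLE_COLUMNS = ["x", "y", "equity_attacking_right"]


def load_equity_table(
    path,
    field: FieldConfig | None = None,
    step: float = 1.0,
    require_coverage: bool = True,
) -> LookupEquity:
    """Load an equity table CSV and (optionally) verify field coverage.

    With ``require_coverage`` every integer-``step`` cell inside the field
    ellipse must be present; missing cells raise :class:`EquityTableError`
    listing (a prefix of) the gaps.
    """
    field = field or FieldConfig()
    df = pd.read_csv(path)
    missing_cols = [c for c in EQUITY_TABLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise EquityTableError(f"{path}: missing column(s) {missing_cols}")
    xs = df["x"].to_numpy(dtype=float)
    ys = df["y"].to_numpy(dtype=float)
    vals = df["equity_attacking_right"].to_numpy(dtype=float)
    x_min, y_min = xs.min(), ys.min()
    nx = int(round((xs.max() - x_min) / step)) + 1
    ny = int(round((ys.max() - y_min) / step)) + 1
    values = np.full((nx, ny), np.nan)
    ix = np.rint((xs - x_min) / step).astype(int)
    iy = np.rint((ys - y_min) / step).astype(int)
    values[ix, iy] = vals
    model = LookupEquity(x_min=x_min, y_min=y_min, step=step, values=values, field=field)
    if require_coverage:
        gx = np.arange(-np.ceil(field.semi_x), np.ceil(field.semi_x) + step / 2, step)
        gy = np.arange(-np.ceil(field.semi_y), np.ceil(field.semi_y) + step / 2, step)
        GX, GY = np.meshgrid(gx, gy, indexing="ij")
        inside = field.contains(GX, GY, margin=0.0)
        covered = ~np.isnan(model._lookup(GX, GY))
        # cells outside the stored bounding box clip to the border; treat
        # them as uncovered unless they genuinely round to a stored cell
        in_box = (
            (GX >= x_min - step / 2)
            & (GX <= xs.max() + step / 2)
            & (GY >= y_min - step / 2)
            & (GY <= ys.max() + step / 2)
        )
        gaps = inside & ~(covered & in_box)
        if np.any(gaps):
            cells = list(zip(GX[gaps].tolist(), GY[gaps].tolist()))
            head = ", ".join(f"({cx:g}, {cy:g})" for cx, cy in cells[:10])
            more = f" and {len(cells) - 10} more" if len(cells) > 10 else ""
            raise EquityTableError(
                f"{path}: table does not cover {len(cells)} field cell(s): {head}{more}"
            )
    return model


def write_equity_table(provider, path, field: FieldConfig | None = None, step: float = 1.0) -> None:
    """Export a provider's attacking-right values on the field grid."""
    field = field or FieldConfig()
    gx = np.arange(-np.ceil(field.semi_x), np.ceil(field.semi_x) + step / 2, step)
    gy = np.arange(-np.ceil(field.semi_y), np.ceil(field.semi_y) + step / 2, step)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    inside = field.contains(GX, GY, margin=0.0)
    vals = np.asarray(provider.evaluate(GX, GY, direction=1))
    df = pd.DataFrame(
        {
            "x": GX[inside].ravel(),
            "y": GY[inside].ravel(),
            "equity_attacking_right": vals[inside].ravel(),
        }
    )
    df.to_csv(path, index=False)
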