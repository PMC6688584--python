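"""Oval field geometry.

The playing surface is modeled as an axis-aligned ellipse centered at the
origin.  The goal-to-goal axis is x; the team in possession always attacks
toward +x by convention, so the attacking goal sits at ``(+length/2, 0)``.
Default axes approximate a large oval stadium (160 m x 129 m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["FieldConfig"]


@dataclass(frozen=True)
class FieldConfig:
    """Elliptical field with configurable axes.

    Parameters
    ----------
    length:
        Full goal-to-goal extent along x, in meters.
    width:
        Full wing-to-wing extent along y, in meters.
    margin:
        Tolerance (meters) allowed outside the boundary before a
        coordinate is considered out of bounds.
    """

    length: float = 160.0
    width: float = 129.0
    margin: float = 2.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("field axes must be positive")

    @property
    def semi_x(self) -> float:
        return self.length / 2.0

    @property
    def semi_y(self) -> float:
        return self.width / 2.0

    def contains(self, x, y, margin: float | None = None):
        """True where (x, y) lies inside the (margin-expanded) ellipse.

        Accepts scalars or arrays; broadcasts like numpy.
        """
        m = self.margin if margin is None else margin
        a = self.semi_x + m
        b = self.semi_y + m
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = (x / a) ** 2 + (y / b) ** 2 <= 1.0
        if inside.ndim == 0:
            return bool(inside)
        return inside

    def goal_center(self, direction: int = 1) -> tuple[float, float]:
        """Goal location for a team attacking toward ``direction`` (+1 / -1)."""
        if direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        return (direction * self.semi_x, 0.0)

    def clamp(self, x: float, y: float, fraction: float = 0.98) -> tuple[float, float]:
        """Pull a point radially inside the ellipse scaled by ``fraction``."""
        a = self.semi_x * fraction
        b = self.semi_y * fraction
        r = math.hypot(x / a, y / b)
        if r <= 1.0 or r == 0.0:
            return (x, y)
        return (x / r, y / r)
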