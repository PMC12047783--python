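"""Discrete grid over the space of motion directions.

Directions live on the full circle (−180°, +180°], with the discrimination
boundary fixed at 0° (rightward horizontal).  Positive directions are the
clockwise ("CW") category, negative directions counter-clockwise ("CCW").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DirectionGrid", "CW", "CCW"]

CW = "CW"
CCW = "CCW"


@dataclass(frozen=True)
class DirectionGrid:
    """Uniform grid of motion directions on (−180°, +180°].

    Parameters
    ----------
    step : float
        Grid spacing in degrees (default 0.1). Must divide 360 evenly.
    boundary : float
        Discrimination boundary; fixed at 0° (rightward horizontal).
    """

    step: float = 0.1
    boundary: float = 0.0
    values: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        n = 360.0 / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("grid step must divide 360 evenly")
        if self.boundary != 0.0:
            raise ValueError("the discrimination boundary is fixed at 0 deg")
        n = int(round(n))
        vals = -180.0 + self.step * np.arange(1, n + 1)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def cw_mask(self) -> np.ndarray:
        """Grid points in the CW category: (0°, 180°).

        The boundary is the full horizontal line, so both 0° and 180°
        belong to neither category; the two half-circles then hold
        equally many grid points.
        """
        return (self.values > 0) & (self.values < 180.0)

    @property
    def ccw_mask(self) -> np.ndarray:
        """Grid points in the CCW category: (−180°, 0°)."""
        return self.values < 0
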