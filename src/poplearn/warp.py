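"""Efficient-coding warp of the motion-direction axis.

A neural "density" function allocates more neurons to directions near the
horizontal boundary.  Its (rescaled) cumulative integral defines a monotone
remapping of the direction axis: tuning curves laid out homogeneously in
the warped coordinate become compressed (denser, narrower) near 0° in
stimulus space.

The density template is

    h(s) = a + 2 * [Phi((s + w_b/2) / sigma_b) - Phi((s - w_b/2) / sigma_b)]

with ``Phi`` the standard cumulative Gaussian: a flat base ``a`` plus a
soft box of height 2 and width ``w_b`` centered on the boundary, with
edge softness ``sigma_b``.  At the boundary h(0) ≈ a + 2, far from it
h → a, so the normalized density peaks at 0°; small ``a`` concentrates
most neurons near the boundary while larger ``a`` flattens the density
toward uniform.  ``h`` is numerically normalized to integrate to 1
before use (with a tiny floor so the density stays strictly positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .grid import DirectionGrid
from .params import WarpSpec

__all__ = ["WarpMap", "build_warp", "identity_warp", "density_template"]


def density_template(s, warp: WarpSpec, bumps=None):
    """Evaluate the unnormalized density h at directions ``s`` (degrees).

    ``bumps`` optionally adds Gaussian density bumps (TC variants), given
    as a ``TuningChangeSpec``.
    """
    s = np.asarray(s, dtype=float)
    h = warp.a + 2.0 * (
        ndtr((s + warp.w_b / 2.0) / warp.sigma_b)
        - ndtr((s - warp.w_b / 2.0) / warp.sigma_b)
    )
    h = np.maximum(h, 1e-12)
    if bumps is not None:
        var = bumps.sigma**2
        norm = bumps.amplitude / np.sqrt(2 * np.pi * var)
        h = h + norm * (
            np.exp(-((s - bumps.center) ** 2) / (2 * var))
            + np.exp(-((s + bumps.center) ** 2) / (2 * var))
        )
    return h


@dataclass(frozen=True)
class WarpMap:
    """Normalized density and the cumulative warp map on a grid.

    ``forward`` maps stimulus direction -> homogeneous (warped)
    coordinate; both axes cover (−180, 180].  ``forward`` is a monotone
    bijection; its slope is proportional to the density.
    """

    grid: DirectionGrid
    density: np.ndarray
    forward: np.ndarray

    def apply(self, s):
        """Map stimulus directions to the homogeneous coordinate."""
        return np.interp(s, self.grid.values, self.forward)

    def invert(self, x):
        """Map homogeneous coordinates back to stimulus directions."""
        return np.interp(x, self.forward, self.grid.values)


def build_warp(warp: WarpSpec | None, grid: DirectionGrid, bumps=None) -> WarpMap:
    """Build the normalized density and cumulative warp map.

    With ``warp=None`` returns the identity map with uniform density.
    """
    s = grid.values
    if warp is None and bumps is None:
        return identity_warp(grid)
    if warp is None:
        raise ValueError("density bumps require a WarpSpec base template")
    h = density_template(s, warp, bumps=bumps)
    total = np.sum(h) * grid.step
    density = h / total
    # Cumulative integral by periodic trapezoid segments: exact identity for
    # a uniform density and F(0)=0 exactly for any symmetric density.
    ext = np.concatenate([density[-1:], density])
    seg_mass = 0.5 * grid.step * (ext[:-1] + ext[1:])
    cum = np.cumsum(seg_mass)
    forward = -180.0 + 360.0 * cum / cum[-1]
    return WarpMap(grid=grid, density=density, forward=forward)


def identity_warp(grid: DirectionGrid) -> WarpMap:
    """Uniform density; the warp map is the identity."""
    n = len(grid)
    return WarpMap(
        grid=grid,
        density=np.full(n, 1.0 / 360.0),
        forward=grid.values.copy(),
    )
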