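"""Unaware likelihood decoding, discrimination, and conditional estimation.

The decoder turns a spike-count vector into a likelihood over motion
direction under its assumed (warp-unaware) population model:

    log L(s) = sum_i r_i * log f_i^decode(s) - sum_i f_i^decode(s).

Before training the assumed gains are homogeneous, the rate-sum term is
constant in s, and the likelihood reduces to the spike-weighted sum of
log tuning curves.  After training the decoder's assumed gain profile is
inhomogeneous, and the rate-sum term actively suppresses evidence for
directions near the boundary (boundary avoidance).

Discrimination compares likelihood mass on the two sides of the boundary
(MAP under the task's symmetric category prior); the log mass ratio ``d``
is the decision variable.  Estimation multiplies the likelihood by a
conditional prior that is 1 on the chosen side and 0 on the other, and
reports the posterior mean plus Gaussian motor noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import DirectionGrid, CW, CCW
from .params import InvalidParameterError
from .population import TuningPopulation
from ._rng import as_rng

__all__ = [
    "LikelihoodFn",
    "decode_likelihood",
    "discriminate",
    "apply_lapse",
    "estimate",
]

D_CAP = 700.0  # cap on |d| in log space


@dataclass(frozen=True)
class LikelihoodFn:
    """Normalized likelihood over motion direction for one trial.

    ``values`` are non-negative and integrate to 1 over the grid
    (Riemann quadrature: sum(values) * step == 1).
    """

    grid: DirectionGrid
    values: np.ndarray

    @property
    def weights(self) -> np.ndarray:
        """Per-gridpoint probability mass (sums to 1)."""
        return self.values * self.grid.step

    def mean(self) -> float:
        return float(np.sum(self.weights * self.grid.values))


def decode_likelihood(r: np.ndarray, pop: TuningPopulation) -> LikelihoodFn:
    """Likelihood of motion direction given spike counts ``r``.

    Uses the decoder's assumed curves (unwarped), which never depend on
    the warp.  An all-zero spike vector yields the prior implied by the
    assumed rate-sum alone (uniform before training).
    """
    r = np.asarray(r)
    if r.shape != (pop.n,):
        raise ValueError(f"expected {pop.n} spike counts, got shape {r.shape}")
    logl = r @ pop.log_tuning_decode - pop.decode_rate_sum
    logl -= logl.max()
    w = np.exp(logl)
    w /= w.sum()
    return LikelihoodFn(grid=pop.grid, values=w / pop.grid.step)


def discriminate(L: LikelihoodFn, rng=None) -> tuple[str, float]:
    """MAP category choice and log-evidence ``d`` = log(CW mass / CCW mass).

    Reports CW iff d > 0; an exact tie is broken by a fair coin from
    ``rng``.  |d| is capped at 700 to avoid overflow.
    """
    w = L.weights
    m_cw = float(w[L.grid.cw_mask].sum())
    m_ccw = float(w[L.grid.ccw_mask].sum())
    with np.errstate(divide="ignore"):
        d = float(np.log(m_cw) - np.log(m_ccw)) if (m_cw > 0 or m_ccw > 0) else 0.0
    d = float(np.clip(d, -D_CAP, D_CAP))
    if d == 0.0:
        choice = CW if as_rng(rng).random() < 0.5 else CCW
    else:
        choice = CW if d > 0 else CCW
    return choice, d


def apply_lapse(p_correct: float, lapse: float) -> float:
    """Scale an accuracy by (1 - lapse), floored at chance (0.5)."""
    if not 0.0 <= lapse <= 1.0:
        raise InvalidParameterError(f"lapse must be in [0, 1], got {lapse}")
    if not 0.0 <= p_correct <= 1.0:
        raise ValueError(f"p_correct must be a probability, got {p_correct}")
    return max(0.5, (1.0 - lapse) * p_correct)


def estimate(
    L: LikelihoodFn, choice: str, sigma_m: float, rng=None, conditional: bool = True
) -> float:
    """Bayes-least-squares estimate conditioned on the category choice.

    The posterior is the likelihood restricted to the chosen side of the
    boundary (conditional prior = indicator of the chosen category),
    renormalized; the reported estimate is its mean plus N(0, sigma_m)
    motor noise.  With ``conditional=False`` the unconditional likelihood
    mean is used (the "no conditional inference" variant).
    """
    w = L.weights
    s = L.grid.values
    if conditional:
        mask = L.grid.cw_mask if choice == CW else L.grid.ccw_mask
        mass = float(w[mask].sum())
        if mass <= 0:
            raise ValueError("zero likelihood mass on the chosen side (degenerate posterior)")
        mu = float((w[mask] * s[mask]).sum() / mass)
    else:
        mu = float((w * s).sum())
    if sigma_m > 0:
        mu += float(as_rng(rng).normal(0.0, sigma_m))
    return mu
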