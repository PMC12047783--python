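"""Encoding population: warped tuning curves, gains, and Poisson spiking.

A population of ``n`` direction-tuned neurons encodes the stimulus.  Each
canonical tuning curve is a single cycle of a raised-cosine bump,
``[cos^2(delta/2)]^p``, with the exponent ``p`` set so the full width at
half maximum equals ``w_t`` (default 71°).  Anchors are equally spaced in
the homogeneous coordinate; the encoding curves are evaluated at warped
grid positions, so more neurons (with narrower tuning) represent
directions near the horizontal boundary.

Training elevates gains along a Gaussian profile *across the population*
— a function of each neuron's anchor in the homogeneous coordinate,
centered on the boundary with SD ``sigma_g`` equal to one inter-neuron
spacing (36° for n=10) by default.  In a strongly warped population the
boosted anchors are the neurons preferring directions within a few
degrees of 0°, so the profile spans roughly the spacing of preferred
directions near the trained stimuli (≈4° at the default neuron count in
that regime).  The neuron anchored at the boundary reaches peak rate
``b + g_post``.

The decoder is unaware of the warp (it assumes anchors are the true
preferred directions) but aware of the training-induced gain change: its
assumed curves carry the same Gaussian gain profile evaluated at the
assumed (homogeneous) positions.  Because those assumed gains are
inhomogeneous after training, the Poisson rate-sum term of the log
likelihood is retained; it suppresses internal evidence near the
boundary after training, which is what lets learning sharpen category
judgments while keeping — or amplifying — the repulsive estimation bias.
For the tuning-change variants no gains change, so the decoder's curves
are identical across sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import DirectionGrid
from .params import ObserverParams, InvalidParameterError
from .warp import WarpMap, build_warp

__all__ = [
    "TuningPopulation",
    "build_population",
    "sample_spikes",
    "tuning_exponent",
    "canonical_tuning",
]

_LOG_FLOOR = 1e-12  # floor on decode curves before taking logs

PRE = "pre"
POST = "post"


def tuning_exponent(w_t: float) -> float:
    """Exponent p such that [cos^2(delta/2)]^p has FWHM ``w_t`` degrees."""
    c = np.cos(np.deg2rad(w_t / 4.0)) ** 2
    return float(np.log(0.5) / np.log(c))


def canonical_tuning(delta, w_t: float):
    """Canonical unit-peak tuning bump at angular offset ``delta`` (degrees)."""
    p = tuning_exponent(w_t)
    c2 = np.cos(np.deg2rad(np.asarray(delta, dtype=float)) / 2.0) ** 2
    return c2**p


@dataclass(frozen=True)
class TuningPopulation:
    """Tuning curves of the encoding population and of the decoder's model.

    ``tuning_encode``: (n, grid) mean rates including warp and session gains.
    ``tuning_decode``: (n, grid) rates the decoder assumes — homogeneous
    (identity warp) positions with the session's assumed gains; never a
    function of the warp.
    """

    grid: DirectionGrid
    session: str
    params: ObserverParams
    warp_map: WarpMap
    preferred_positions: np.ndarray  # anchors in the homogeneous coordinate
    preferred_directions: np.ndarray  # anchors mapped to stimulus space
    gains: np.ndarray  # true encoding gains
    decode_gains: np.ndarray  # gains the decoder assumes (warp-unaware)
    tuning_encode: np.ndarray
    tuning_decode: np.ndarray
    log_tuning_decode: np.ndarray
    decode_rate_sum: np.ndarray  # sum over neurons of assumed rates, per gridpoint

    @property
    def n(self) -> int:
        return self.preferred_positions.size

    def encode_rates(self, s) -> np.ndarray:
        """Mean firing rates (n,) or (n, len(s)) at stimulus direction(s) s."""
        shared = self.params.shared
        scalar = np.ndim(s) == 0
        x = np.atleast_1d(self.warp_map.apply(s))
        delta = self.preferred_positions[:, None] - x[None, :]
        rates = shared.b + self.gains[:, None] * canonical_tuning(delta, shared.w_t)
        return rates[:, 0] if scalar else rates


def _session_gains(params: ObserverParams, anchors: np.ndarray) -> np.ndarray:
    """Post-training gains: Gaussian profile over the homogeneous coordinate."""
    sh = params.shared
    profile = np.exp(-(anchors**2) / (2.0 * sh.sigma_g**2))
    return params.g_pre + (params.g_post - params.g_pre) * profile


def build_population(
    params: ObserverParams, session: str, grid: DirectionGrid | None = None
) -> TuningPopulation:
    """Construct the encoding/decoding tuning curves for one session.

    ``session`` is "pre" or "post".  Post-training either elevates gains
    along the Gaussian profile (gain-change mechanism) or, for TC-variant
    parameters, adds density bumps at the trained directions.
    """
    if session not in (PRE, POST):
        raise InvalidParameterError(f"session must be 'pre' or 'post', got {session!r}")
    if grid is None:
        grid = DirectionGrid()
    sh = params.shared

    bumps = params.tuning_change if session == POST else None
    wmap = build_warp(params.warp, grid, bumps=bumps)

    n = sh.n
    anchors = -180.0 + 360.0 * np.arange(n) / n  # includes 0 for even n
    pref_dir = wmap.invert(anchors)

    if session == POST and params.tuning_change is None:
        # The same per-neuron gains enter encoding and the decoder's assumed
        # curves: the decoder knows the gain boost but not the warp.
        gains = _session_gains(params, anchors)
        decode_gains = gains
    else:
        gains = np.full(n, params.g_pre)
        decode_gains = np.full(n, params.g_pre)

    x = wmap.forward  # warped position of every grid point
    delta_enc = anchors[:, None] - x[None, :]
    tuning_encode = sh.b + gains[:, None] * canonical_tuning(delta_enc, sh.w_t)

    delta_dec = anchors[:, None] - grid.values[None, :]
    tuning_decode = sh.b + decode_gains[:, None] * canonical_tuning(delta_dec, sh.w_t)
    log_decode = np.log(np.maximum(tuning_decode, _LOG_FLOOR))

    return TuningPopulation(
        grid=grid,
        session=session,
        params=params,
        warp_map=wmap,
        preferred_positions=anchors,
        preferred_directions=pref_dir,
        gains=gains,
        decode_gains=decode_gains,
        tuning_encode=tuning_encode,
        tuning_decode=tuning_decode,
        log_tuning_decode=log_decode,
        decode_rate_sum=tuning_decode.sum(axis=0),
    )


def sample_spikes(pop: TuningPopulation, s: float, rng) -> np.ndarray:
    """Draw one population response: independent Poisson counts per neuron."""
    rates = pop.encode_rates(float(s))
    return rng.poisson(rates)
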