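"""Behavioral loss: L1 on discrimination accuracy + energy distance on estimates.

The fit target for one observer is the weighted sum of (1) absolute
differences between data and model discrimination accuracy and (2) the
energy distance between data and model estimate distributions, summed
over the three collapsed stimulus magnitudes (2°, 4°, 8°) and the two
sessions.  The model side is obtained by Monte-Carlo simulation, so the
loss is stochastic; identical seeds give bit-identical values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import DirectionGrid
from .params import ObserverParams
from .population import build_population
from .simulate import simulate_trials, TASK_DISC, TASK_EST
from .decoding import apply_lapse
from ._rng import named_streams, child_seed

__all__ = [
    "LossSpec",
    "ObserverData",
    "ModelBehavior",
    "energy_distance",
    "behavioral_loss",
    "compute_loss_weights",
    "simulate_model_behavior",
]

MAGNITUDES = (2.0, 4.0, 8.0)
SESSIONS = ("pre", "post")


class MissingConditionError(ValueError):
    """The trial table lacks a (session, task, magnitude) cell needed to fit."""


@dataclass(frozen=True)
class LossSpec:
    """Configuration of the behavioral loss.

    ``w_disc``/``w_est`` weight the two terms (normalized once per
    observer and then frozen across model variants); ``trial_budget`` is
    the number of simulated trials per stimulus magnitude and session
    (1500 in the study's own fits); ``grid_step`` sets the decoding-grid
    resolution used inside loss evaluations.
    """

    w_disc: float = 1.0
    w_est: float = 1.0
    trial_budget: int = 1500
    grid_step: float = 1.0

    def __post_init__(self):
        if self.w_disc < 0 or self.w_est < 0:
            raise ValueError("loss weights must be non-negative")
        if self.trial_budget < 100:
            raise ValueError("trial_budget must be >= 100")

    def grid(self) -> DirectionGrid:
        return DirectionGrid(self.grid_step)


def energy_distance(x, y) -> float:
    """Energy distance between two 1-D samples (V-statistic estimator).

    D = 2 E|X - Y| - E|X - X'| - E|Y - Y'| with all expectations taken
    over independent ordered pairs (diagonal included), which is
    non-negative up to numerical noise and zero iff the empirical
    distributions coincide.  Computed in O((n+m) log(n+m)) via sorting.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("energy_distance requires nonempty samples")
    return 2.0 * _mean_abs_cross(x, y) - _mean_abs_within(x) - _mean_abs_within(y)


def _mean_abs_within(x: np.ndarray) -> float:
    n = x.size
    if n == 1:
        return 0.0
    c = np.sort(x)
    i = np.arange(n)
    pair_sum = np.sum((2 * i - n + 1) * c)  # sum over i<j of c_j - c_i
    return 2.0 * pair_sum / (n * n)


def _mean_abs_cross(x: np.ndarray, y: np.ndarray) -> float:
    xs = np.sort(x)
    cx = np.concatenate([[0.0], np.cumsum(xs)])
    n, m = xs.size, y.size
    k = np.searchsorted(xs, y, side="right")
    total = np.sum(y * (2 * k - n) - 2 * cx[k]) + m * cx[n]
    return total / (n * m)


@dataclass
class ObserverData:
    """Collapsed per-condition behavioral data for one observer.

    ``disc_acc[(mag, session)]`` is the discrimination accuracy and
    ``estimates[(mag, session)]`` the collapsed (sign-corrected)
    estimation responses at stimulus magnitude ``mag``.
    """

    disc_acc: dict = field(default_factory=dict)
    disc_n: dict = field(default_factory=dict)
    estimates: dict = field(default_factory=dict)

    @classmethod
    def from_trials(cls, trials: pd.DataFrame) -> "ObserverData":
        """Collapse a tidy trial table (one observer) into fit cells.

        Downward trials are negated so positive responses are on the
        correct-category side; every (magnitude × session × task) cell
        must be present.
        """
        out = cls()
        for session in SESSIONS:
            for mag in MAGNITUDES:
                sel = (
                    (trials["session"] == session)
                    & (np.abs(trials["stimulus_deg"]) == mag)
                )
                disc = trials[sel & (trials["task"] == TASK_DISC)]
                est = trials[sel & (trials["task"] == TASK_EST)]
                if len(disc) == 0 or len(est) == 0:
                    raise MissingConditionError(
                        f"missing data for magnitude {mag}, session {session!r} "
                        f"(disc n={len(disc)}, est n={len(est)})"
                    )
                correct = disc["response"].to_numpy() == disc["category"].to_numpy()
                out.disc_acc[(mag, session)] = float(np.mean(correct))
                out.disc_n[(mag, session)] = int(len(disc))
                vals = est["response"].to_numpy(dtype=float)
                sign = np.where(est["stimulus_deg"].to_numpy() < 0, -1.0, 1.0)
                out.estimates[(mag, session)] = vals * sign
        return out


@dataclass
class ModelBehavior:
    """Simulated model behavior in the same cell structure as ObserverData."""

    disc_acc: dict
    estimates: dict


def simulate_model_behavior(
    params: ObserverParams,
    spec: LossSpec,
    seed: int,
    conditional: bool = True,
    magnitudes=MAGNITUDES,
) -> ModelBehavior:
    """Monte-Carlo model behavior per (magnitude × session).

    By the model's mirror symmetry about the boundary, only positive
    stimuli are simulated; each cell's trials provide both the (lapsed)
    discrimination accuracy and the estimate sample.
    """
    grid = spec.grid()
    acc, est = {}, {}
    for session in SESSIONS:
        pop = build_population(params, session, grid)
        streams = named_streams(child_seed(seed, session), "spikes", "ties", "motor")
        for mag in magnitudes:
            ch, _, e = simulate_trials(
                pop,
                mag,
                spec.trial_budget,
                streams["spikes"],
                streams["ties"],
                streams["motor"],
                params.shared.sigma_m,
                conditional=conditional,
                want_estimates=True,
            )
            acc[(mag, session)] = apply_lapse(float(np.mean(ch)), params.lapse)
            est[(mag, session)] = e
    return ModelBehavior(disc_acc=acc, estimates=est)


def loss_terms(
    data: ObserverData,
    params: ObserverParams,
    spec: LossSpec,
    seed: int,
    conditional: bool = True,
) -> tuple[float, float]:
    """Unweighted (discrimination L1, energy distance) loss terms."""
    model = simulate_model_behavior(params, spec, seed, conditional=conditional)
    t_disc = 0.0
    t_est = 0.0
    for key in data.disc_acc:
        t_disc += abs(data.disc_acc[key] - model.disc_acc[key])
        t_est += energy_distance(data.estimates[key], model.estimates[key])
    return t_disc, t_est


def behavioral_loss(
    data: ObserverData,
    params: ObserverParams,
    spec: LossSpec,
    seed: int,
    conditional: bool = True,
) -> float:
    """Weighted behavioral loss for one observer and one parameter set."""
    t_disc, t_est = loss_terms(data, params, spec, seed, conditional=conditional)
    return spec.w_disc * t_disc + spec.w_est * t_est


def compute_loss_weights(
    data: ObserverData,
    params_init: ObserverParams,
    spec: LossSpec,
    seed: int,
    conditional: bool = True,
) -> tuple[float, float]:
    """Normalization weights that bring both loss terms near 1 at θ_init.

    Evaluated once per observer on an initial parameter set and then
    frozen — in particular across model variants, so cross-validated
    losses remain comparable between models.
    """
    t_disc, t_est = loss_terms(data, params_init, spec, seed, conditional=conditional)
    weights = []
    for name, term in (("discrimination", t_disc), ("estimation", t_est)):
        if term <= 0:
            warnings.warn(
                f"{name} loss term is zero at the normalization point; "
                "falling back to weight 1"
            )
            weights.append(1.0)
        else:
            weights.append(1.0 / term)
    return tuple(weights)
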