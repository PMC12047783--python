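"""Forward simulation of observer behavior.

``simulate_block`` runs the full generative chain — Poisson spiking,
unaware likelihood decoding, discrimination (with lapse applied to the
aggregate accuracy), and conditional estimation with motor noise — for a
block of trials at enumerated stimulus directions, returning tidy
trial-level rows and per-stimulus summaries.

The inner loop is vectorized over trials: for a block of T trials the
spike matrix (T, n) is multiplied against the decoder's log tuning curves
(n, G) to give all T log likelihoods at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import DirectionGrid, CW, CCW
from .params import ObserverParams
from .population import build_population, TuningPopulation
from .decoding import apply_lapse, D_CAP
from ._rng import named_streams

__all__ = [
    "TASK_DISC",
    "TASK_EST",
    "TRIAL_COLUMNS",
    "BlockSummary",
    "simulate_trials",
    "simulate_block",
    "draw_task_trials",
]

TASK_DISC = "disc"
TASK_EST = "est"

TRIAL_COLUMNS = [
    "observer_id",
    "group",
    "session",
    "task",
    "stimulus_deg",
    "category",
    "response",
    "trial_index",
    "seed",
]

STIMULUS_MAGNITUDES = (2.0, 4.0, 8.0)

_CHUNK = 4096


def simulate_trials(
    pop: TuningPopulation,
    stimulus: float,
    n_trials: int,
    rng_spikes,
    rng_tie,
    rng_motor,
    sigma_m: float,
    conditional: bool = True,
    want_estimates: bool = True,
):
    """Vectorized simulation of ``n_trials`` at one stimulus direction.

    Returns ``(choice_cw, d, estimates)``; ``estimates`` is None when
    ``want_estimates`` is False.
    """
    grid = pop.grid
    s = grid.values
    cw = grid.cw_mask.astype(float)
    ccw = grid.ccw_mask.astype(float)
    s_cw = s * cw
    s_ccw = s * ccw
    rates = pop.encode_rates(float(stimulus))
    logf = pop.log_tuning_decode  # (n, G)
    rate_sum = pop.decode_rate_sum  # (G,)

    choice_cw = np.empty(n_trials, dtype=bool)
    d_all = np.empty(n_trials)
    est = np.empty(n_trials) if want_estimates else None

    done = 0
    while done < n_trials:
        t = min(_CHUNK, n_trials - done)
        R = rng_spikes.poisson(rates, size=(t, rates.size))
        W = R @ logf
        W -= rate_sum[None, :]
        W -= W.max(axis=1, keepdims=True)
        E = np.exp(W)
        m_cw = E @ cw
        m_ccw = E @ ccw
        with np.errstate(divide="ignore"):
            d = np.log(m_cw) - np.log(m_ccw)
        d = np.clip(np.nan_to_num(d, nan=0.0, posinf=D_CAP, neginf=-D_CAP), -D_CAP, D_CAP)
        ch = d > 0
        ties = d == 0
        if ties.any():
            ch[ties] = rng_tie.random(int(ties.sum())) < 0.5
        sl = slice(done, done + t)
        choice_cw[sl] = ch
        d_all[sl] = d
        if want_estimates:
            if conditional:
                with np.errstate(invalid="ignore", divide="ignore"):
                    mu_cw = (E @ s_cw) / m_cw
                    mu_ccw = (E @ s_ccw) / m_ccw
                mu = np.where(ch, mu_cw, mu_ccw)
            else:
                mu = (E @ s) / E.sum(axis=1)
            if sigma_m > 0:
                mu = mu + rng_motor.normal(0.0, sigma_m, size=t)
            est[sl] = mu
        done += t
    return choice_cw, d_all, est


@dataclass
class BlockSummary:
    """Per-stimulus summaries of one simulated block."""

    p_correct: dict[float, float] = field(default_factory=dict)  # lapsed accuracy
    raw_accuracy: dict[float, float] = field(default_factory=dict)
    estimates: dict[float, np.ndarray] = field(default_factory=dict)


def simulate_block(
    params: ObserverParams,
    session: str,
    task: str,
    stimuli,
    trials_per_stimulus: int,
    seed: int,
    grid: DirectionGrid | None = None,
    conditional: bool = True,
    observer_id: str = "sim",
    group: str = "none",
) -> tuple[pd.DataFrame, BlockSummary]:
    """Simulate one testing block at enumerated stimulus directions.

    Each stimulus in ``stimuli`` is shown ``trials_per_stimulus`` times;
    the trial's true category follows the sign of the stimulus.  The
    lapse parameter scales the aggregate discrimination accuracy in the
    summary (it does not flip individual simulated choices).
    """
    if task not in (TASK_DISC, TASK_EST):
        raise ValueError(f"task must be '{TASK_DISC}' or '{TASK_EST}', got {task!r}")
    if len(stimuli) == 0:
        raise ValueError("stimuli must be nonempty")
    pop = build_population(params, session, grid)
    streams = named_streams(seed, "spikes", "ties", "motor")
    want_est = task == TASK_EST

    frames = []
    summary = BlockSummary()
    for stim in stimuli:
        ch, _, est = simulate_trials(
            pop,
            stim,
            trials_per_stimulus,
            streams["spikes"],
            streams["ties"],
            streams["motor"],
            params.shared.sigma_m,
            conditional=conditional,
            want_estimates=want_est,
        )
        true_cw = stim > 0
        correct = ch == true_cw
        acc = float(correct.mean())
        summary.raw_accuracy[stim] = acc
        summary.p_correct[stim] = apply_lapse(acc, params.lapse)
        if want_est:
            summary.estimates[stim] = est
        resp = est if want_est else np.where(ch, CW, CCW)
        frames.append(
            pd.DataFrame(
                {
                    "observer_id": observer_id,
                    "group": group,
                    "session": session,
                    "task": task,
                    "stimulus_deg": float(stim),
                    "category": CW if true_cw else CCW,
                    "response": resp,
                    "trial_index": np.arange(trials_per_stimulus),
                    "seed": seed,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]
    return table, summary


def draw_task_trials(n: int, rng, magnitudes=STIMULUS_MAGNITUDES):
    """Draw (category, stimulus) pairs from the task's generative process.

    Category is CW with probability 0.5; the stimulus magnitude is uniform
    over ``magnitudes`` and its sign follows the category, so the overall
    stimulus distribution is uniform over the six signed directions.
    """
    cw = rng.random(n) < 0.5
    mags = rng.choice(np.asarray(magnitudes, dtype=float), size=n)
    stimuli = np.where(cw, mags, -mags)
    categories = np.where(cw, CW, CCW)
    return categories, stimuli
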