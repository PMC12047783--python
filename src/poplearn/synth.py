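"""Synthetic-study generation.

Two generators:

* a *mechanistic* one, which draws per-observer model parameters and runs
  the observer model itself over the study's 3-group × 2-session ×
  2-task × 6-direction design (7 observers per group, 60 trials per
  signed direction per task per session), and
* a *parametric* two-component Gaussian mixture over estimates, used to
  unit-test the statistics in isolation with known primary/secondary
  modes.

Both are seeded and reproduce bit-exactly; the mechanistic generator
returns a ground-truth sidecar sufficient to re-simulate the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import DirectionGrid, CW
from .params import ObserverParams, SharedParams, WarpSpec
from .simulate import simulate_block, TASK_DISC, TASK_EST, TRIAL_COLUMNS
from ._rng import child_seed

__all__ = [
    "StudyDesign",
    "MixtureSpec",
    "sample_observer_params",
    "generate_study",
    "generate_mixture_estimates",
]

GROUPS = ("control", "disc_train", "est_train")

# Documented generator ranges for per-observer parameter draws, spanning
# near-unbiased to highly biased observers.  The gain range is calibrated so
# pre-test discrimination accuracy falls in the study's reported band
# (~0.65-0.90 across 2-8 deg) rather than saturating.
PARAM_RANGES = {
    "a": (0.0, 2.0),
    "w_b": (10.0, 30.0),
    "sigma_b": (1.0, 6.0),
    "g_pre": (3.0, 10.0),
    "lapse": (0.0, 0.1),
    "sigma_m": (1.0, 4.0),
    "gain_factor": (1.5, 3.0),  # g_post / g_pre for training groups
}


@dataclass(frozen=True)
class StudyDesign:
    """Shape of the pre/post behavioral study."""

    observers_per_group: dict = field(
        default_factory=lambda: {g: 7 for g in GROUPS}
    )
    stimuli: tuple = (-8.0, -4.0, -2.0, 2.0, 4.0, 8.0)
    trials_per_direction: int = 60  # per task and session
    sessions: tuple = ("pre", "post")

    def __post_init__(self):
        if self.trials_per_direction < 1:
            raise ValueError("trials_per_direction must be >= 1")
        s = np.asarray(self.stimuli)
        if not np.allclose(np.sort(s), np.sort(-s)):
            raise ValueError("stimulus directions must be symmetric about 0")

    @property
    def n_trials(self) -> int:
        n_obs = sum(self.observers_per_group.values())
        return (
            n_obs
            * len(self.sessions)
            * 2  # tasks
            * len(self.stimuli)
            * self.trials_per_direction
        )


def sample_observer_params(
    group: str, rng, learning_effect: str = "gain"
) -> ObserverParams:
    """Draw one observer's generative parameters.

    Control observers (or ``learning_effect="none"``) have g_post ==
    g_pre exactly; training-group observers draw a gain factor in the
    documented [1.5, 3] range.
    """
    u = {k: rng.uniform(*v) for k, v in PARAM_RANGES.items()}
    trained = group in ("disc_train", "est_train") and learning_effect == "gain"
    g_post = u["g_pre"] * u["gain_factor"] if trained else u["g_pre"]
    return ObserverParams(
        g_pre=u["g_pre"],
        g_post=g_post,
        lapse=u["lapse"],
        warp=WarpSpec(a=u["a"], w_b=u["w_b"], sigma_b=u["sigma_b"]),
        shared=SharedParams(sigma_m=u["sigma_m"]),
    )


def _apply_disc_lapses(table: pd.DataFrame, lapse: float, rng) -> pd.DataFrame:
    """Realize lapses as per-trial incorrect responses on disc trials.

    The model treats lapses as scaling aggregate accuracy by (1 − λ); at
    the single-trial level that corresponds to replacing a fraction λ of
    responses with the incorrect label.
    """
    if lapse <= 0:
        return table
    disc = table["task"] == TASK_DISC
    flip = disc & (rng.random(len(table)) < lapse)
    wrong = np.where(table.loc[flip, "category"] == CW, "CCW", "CW")
    table.loc[flip, "response"] = wrong
    return table


def generate_study(
    design: StudyDesign | None = None,
    seed: int = 0,
    grid_step: float = 0.5,
    learning_effect: str = "gain",
) -> tuple[pd.DataFrame, dict]:
    """Simulate a complete synthetic study.

    Returns ``(trials, sidecar)`` where ``sidecar`` records the design,
    seed, and each observer's generative parameters — enough to
    re-simulate the identical table.
    """
    design = design or StudyDesign()
    frames = []
    sidecar = {
        "seed": int(seed),
        "grid_step": grid_step,
        "learning_effect": learning_effect,
        "trials_per_direction": design.trials_per_direction,
        "observers": {},
    }
    grid = DirectionGrid(grid_step)
    for group in design.observers_per_group:
        for i in range(design.observers_per_group[group]):
            obs_id = f"{group}_{i + 1:02d}"
            obs_seed = child_seed(seed, f"obs-{obs_id}")
            prng = np.random.default_rng(child_seed(obs_seed, "params"))
            params = sample_observer_params(group, prng, learning_effect)
            sidecar["observers"][obs_id] = params.to_dict()
            lapse_rng = np.random.default_rng(child_seed(obs_seed, "lapse"))
            for session in design.sessions:
                for task in (TASK_DISC, TASK_EST):
                    tbl, _ = simulate_block(
                        params,
                        session,
                        task,
                        design.stimuli,
                        design.trials_per_direction,
                        seed=child_seed(obs_seed, f"{session}-{task}"),
                        grid=grid,
                        observer_id=obs_id,
                        group=group,
                    )
                    if task == TASK_DISC:
                        tbl = _apply_disc_lapses(tbl, params.lapse, lapse_rng)
                    frames.append(tbl)
    trials = pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]
    return trials, sidecar


@dataclass(frozen=True)
class MixtureSpec:
    """Two-component mixture of estimates with a misclassified mode.

    ``mu_pos`` is the primary (correct-side) mode, ``mu_neg`` the
    secondary mode on the incorrect side, ``w_neg`` the misclassification
    weight.
    """

    mu_pos: float = 15.0
    mu_neg: float = -9.0
    sigma: float = 3.0
    w_neg: float = 0.25

    def __post_init__(self):
        if not (self.mu_pos > 0 > self.mu_neg):
            raise ValueError("need mu_pos > 0 > mu_neg")
        if not 0.0 <= self.w_neg <= 1.0:
            raise ValueError("w_neg must be in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def generate_mixture_estimates(spec: MixtureSpec, n: int, rng) -> np.ndarray:
    """Draw ``n`` estimates from w·N(mu_neg, σ²) + (1−w)·N(mu_pos, σ²)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    neg = rng.random(n) < spec.w_neg
    mu = np.where(neg, spec.mu_neg, spec.mu_pos)
    return rng.normal(mu, spec.sigma)
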