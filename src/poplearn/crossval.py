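"""Iterated k-fold cross-validated model comparison.

Trials are partitioned into k stratified folds (strata: session × task ×
stimulus direction) independently in each iteration; each variant is fit
on k−1 folds and its loss evaluated on the held-out fold with the same
frozen normalization weights for every variant, so test losses are
comparable across models.  The study's setting is k=3 with 34 iterations
(102 fold evaluations); desk-scale runs use fewer iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import SharedParams
from .loss import LossSpec, ObserverData, behavioral_loss, compute_loss_weights
from .fitting import fit_observer, initial_guess
from .variants import make_variant
from ._rng import child_seed

__all__ = ["CVResult", "cross_validate_models", "stratified_folds"]


@dataclass
class CVResult:
    """Per-fold losses and per-variant summaries of one CV comparison."""

    records: pd.DataFrame  # variant, iteration, fold, train_loss, test_loss
    weights: tuple

    def summary(self) -> pd.DataFrame:
        out = (
            self.records.groupby("variant")[["train_loss", "test_loss"]]
            .mean()
            .reset_index()
        )
        if "full" in set(out["variant"]):
            ref = float(out.loc[out["variant"] == "full", "test_loss"].iloc[0])
            out["delta_test_vs_full"] = out["test_loss"] - ref
        return out


def stratified_folds(trials: pd.DataFrame, k: int, rng) -> np.ndarray:
    """Assign each trial a fold in 0..k-1, stratified by condition cell.

    Raises if any (session × task × stimulus) stratum has fewer than k
    trials, naming the stratum.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    fold = np.empty(len(trials), dtype=int)
    keys = list(zip(trials["session"], trials["task"], trials["stimulus_deg"]))
    idx = pd.Series(np.arange(len(trials)), index=pd.MultiIndex.from_tuples(keys))
    for stratum, members in idx.groupby(level=[0, 1, 2]):
        positions = members.to_numpy()
        if positions.size < k:
            raise ValueError(
                f"stratum session={stratum[0]!r} task={stratum[1]!r} "
                f"stimulus={stratum[2]} has {positions.size} < k={k} trials"
            )
        perm = rng.permutation(positions)
        fold[perm] = np.arange(positions.size) % k
    return fold


def cross_validate_models(
    trials: pd.DataFrame,
    variants,
    k: int = 3,
    iterations: int = 5,
    spec: LossSpec | None = None,
    seed: int = 0,
    n_restarts: int = 2,
    budget: int = 120,
    shared: SharedParams | None = None,
    warm_budget: int = 300,
    warm_restarts: int = 2,
) -> CVResult:
    """Compare model variants by iterated stratified k-fold CV loss.

    ``trials`` is the tidy trial table of a single observer.  Loss
    weights are computed once from the full data at the full model's
    seeded initial point and frozen for every variant, fold and
    iteration.

    Each variant is first fit once on the complete data
    (``warm_budget`` evaluations × ``warm_restarts``); the per-fold fits
    then refine that solution on the training folds.  The warm start is
    applied identically to every variant, so the *relative* CV losses
    remain a fair comparison while per-fold budgets stay small.
    """
    spec = spec or LossSpec()
    shared = shared or SharedParams()
    variants = [make_variant(v) if isinstance(v, str) else v for v in variants]

    full_data = ObserverData.from_trials(trials)
    ref_variant = make_variant("full")
    theta0 = initial_guess(ref_variant, seed)
    weights = compute_loss_weights(
        full_data,
        ref_variant.build_params(theta0, shared),
        spec,
        child_seed(seed, "weights"),
    )
    wspec = LossSpec(
        w_disc=weights[0],
        w_est=weights[1],
        trial_budget=spec.trial_budget,
        grid_step=spec.grid_step,
    )

    warm = {}
    for variant in variants:
        warm[variant.name] = fit_observer(
            full_data,
            variant,
            spec=wspec,
            n_restarts=warm_restarts,
            budget=warm_budget,
            seed=child_seed(seed, f"warm-{variant.name}"),
            shared=shared,
            weights=weights,
        ).best_x

    rng = np.random.default_rng(child_seed(seed, "folds"))
    records = []
    for it in range(iterations):
        fold_of = stratified_folds(trials, k, rng)
        for fold in range(k):
            train = ObserverData.from_trials(trials[fold_of != fold])
            test = ObserverData.from_trials(trials[fold_of == fold])
            for variant in variants:
                fit = fit_observer(
                    train,
                    variant,
                    spec=wspec,
                    n_restarts=n_restarts,
                    budget=budget,
                    seed=child_seed(seed, f"fit-{variant.name}-{it}-{fold}"),
                    shared=shared,
                    weights=weights,
                    x0=warm[variant.name],
                )
                params = variant.build_params(fit.best_x, shared)
                eval_seed = child_seed(seed, f"eval-{it}-{fold}")
                test_loss = behavioral_loss(
                    test, params, wspec, eval_seed, conditional=variant.conditional
                )
                records.append(
                    {
                        "variant": variant.name,
                        "iteration": it,
                        "fold": fold,
                        "train_loss": fit.best_loss,
                        "test_loss": float(test_loss),
                    }
                )
    return CVResult(records=pd.DataFrame(records), weights=tuple(weights))
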