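"""End-to-end pipeline: simulate (or load) → stats → fit → compare.

Each stage writes its outputs (CSV tables, JSON reports) into the run
directory together with the seed and a configuration hash, so a run can
be reproduced exactly from its artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .io import RunConfig, read_trials, write_trials
from .loss import LossSpec, ObserverData
from .fitting import fit_observer
from .crossval import cross_validate_models
from .stats import (
    collapse_by_category,
    bin_estimate_counts,
    cluster_mass_test,
    summarize_study,
)
from .synth import StudyDesign, generate_study
from ._rng import child_seed

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are preserved."""


def _dump(obj, path: Path):
    path.write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis pipeline; returns paths of written artifacts.

    Stages: data (simulate or load), stats (summary tables, cluster
    test), fit (full model, first ``fit_observers`` observers of the
    stats group), compare (cross-validated variants, first observer).
    Any stage failure aborts with the stage name; artifacts already
    written stay on disk.
    """
    out = Path(config.out_dir)
    if not out.exists():
        logger.info("creating output directory %s", out)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "runtimes_s": {},
    }
    artifacts = {}
    stage = "data"
    try:
        t0 = time.time()
        if config.data:
            trials = read_trials(config.data)
        else:
            design = StudyDesign(
                observers_per_group={
                    g: config.observers_per_group
                    for g in ("control", "disc_train", "est_train")
                },
                trials_per_direction=config.trials_per_direction,
            )
            trials, sidecar = generate_study(
                design, seed=config.seed, grid_step=config.grid_step
            )
            _dump(sidecar, out / "ground_truth.json")
            artifacts["ground_truth"] = str(out / "ground_truth.json")
        write_trials(trials, out / "trials.csv")
        artifacts["trials"] = str(out / "trials.csv")
        meta["runtimes_s"][stage] = round(time.time() - t0, 2)

        stage = "stats"
        t0 = time.time()
        rng = np.random.default_rng(child_seed(config.seed, "stats"))
        summary = summarize_study(trials, n_perm=config.n_perm, rng=rng)
        for name, table in summary.items():
            table.to_csv(out / f"summary_{name}.csv", index=False)
            artifacts[f"summary_{name}"] = str(out / f"summary_{name}.csv")
        collapsed = collapse_by_category(trials)
        grp = collapsed[collapsed["group"] == config.stats_group]
        counts = bin_estimate_counts(grp)
        cres = cluster_mass_test(
            counts,
            n_perm=config.n_perm,
            rng=np.random.default_rng(child_seed(config.seed, "cluster")),
        )
        _dump(
            {
                "seed": config.seed,
                "config_digest": config.digest(),
                "group": config.stats_group,
                "z": cres.z,
                "bin_edges": cres.bin_edges,
                "clusters": cres.clusters,
            },
            out / "cluster_test.json",
        )
        artifacts["cluster_test"] = str(out / "cluster_test.json")
        meta["runtimes_s"][stage] = round(time.time() - t0, 2)

        stage = "fit"
        t0 = time.time()
        spec = LossSpec(
            trial_budget=config.trial_budget, grid_step=config.fit_grid_step
        )
        grp_trials = trials[trials["group"] == config.stats_group]
        fit_ids = sorted(grp_trials["observer_id"].unique())[: config.fit_observers]
        fits = {}
        for obs in fit_ids:
            data = ObserverData.from_trials(
                grp_trials[grp_trials["observer_id"] == obs]
            )
            res = fit_observer(
                data,
                "full",
                spec=spec,
                n_restarts=config.n_restarts,
                budget=config.fit_budget,
                seed=child_seed(config.seed, f"fit-{obs}"),
            )
            fits[obs] = res.to_dict()
        _dump(
            {"seed": config.seed, "config_digest": config.digest(), "fits": fits},
            out / "fits.json",
        )
        artifacts["fits"] = str(out / "fits.json")
        meta["runtimes_s"][stage] = round(time.time() - t0, 2)

        stage = "compare"
        t0 = time.time()
        obs = fit_ids[0]
        cv = cross_validate_models(
            grp_trials[grp_trials["observer_id"] == obs],
            config.variants,
            k=config.cv_k,
            iterations=config.cv_iterations,
            spec=spec,
            seed=child_seed(config.seed, "cv"),
            budget=config.fit_budget,
            warm_budget=config.fit_budget,
            warm_restarts=config.n_restarts,
        )
        cv.records.to_csv(out / "cv_records.csv", index=False)
        cv.summary().to_csv(out / "cv_summary.csv", index=False)
        artifacts["cv_records"] = str(out / "cv_records.csv")
        artifacts["cv_summary"] = str(out / "cv_summary.csv")
        meta["runtimes_s"][stage] = round(time.time() - t0, 2)
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        _dump(meta, out / "run_meta.json")
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    meta["artifacts"] = artifacts
    _dump(meta, out / "run_meta.json")
    artifacts["run_meta"] = str(out / "run_meta.json")
    return artifacts
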