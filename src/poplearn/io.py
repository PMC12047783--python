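"""Trial-table and configuration IO.

Trial tables are RFC-4180 CSV with the fixed schema

    observer_id, group, session, task, stimulus_deg, category,
    response, trial_index, seed

where ``response`` is CW/CCW for discrimination rows and degrees for
estimation rows (NA allowed only where a task makes the field
inapplicable).  Configurations are flat YAML or JSON mappings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import CW, CCW
from .simulate import TRIAL_COLUMNS, TASK_DISC, TASK_EST

__all__ = ["SchemaError", "read_trials", "write_trials", "RunConfig", "load_config"]

_VALID_SESSIONS = {"pre", "post"}
_VALID_TASKS = {TASK_DISC, TASK_EST}
_VALID_CHOICES = {CW, CCW}


class SchemaError(ValueError):
    """The file does not match the trial-table schema."""


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Raises :class:`SchemaError` naming missing/extra columns; malformed
    rows are rejected with their (1-based, header-inclusive) line
    numbers.
    """
    df = pd.read_csv(path, dtype={"observer_id": str, "group": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if missing or extra:
        raise SchemaError(
            f"trial table schema mismatch: missing columns {missing}, "
            f"unexpected columns {extra}"
        )
    bad_lines = []
    session_ok = df["session"].isin(_VALID_SESSIONS)
    task_ok = df["task"].isin(_VALID_TASKS)
    stim = pd.to_numeric(df["stimulus_deg"], errors="coerce")
    cat_ok = df["category"].isin(_VALID_CHOICES)
    resp = df["response"].astype(str)
    disc = df["task"] == TASK_DISC
    resp_num = pd.to_numeric(df["response"], errors="coerce")
    resp_ok = np.where(disc, resp.isin(_VALID_CHOICES), ~resp_num.isna())
    ok = session_ok & task_ok & ~stim.isna() & cat_ok & resp_ok
    if not ok.all():
        bad_lines = (df.index[~ok] + 2).tolist()  # +1 header, +1 one-based
        raise SchemaError(
            f"{len(bad_lines)} malformed trial rows at lines "
            f"{bad_lines[:20]}{'...' if len(bad_lines) > 20 else ''}"
        )
    df["stimulus_deg"] = stim
    df.loc[~disc, "response"] = resp_num[~disc]
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV with the canonical column order."""
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Every count must be positive; the seed is recorded in all output
    artifacts together with a hash of this configuration.
    """

    seed: int = 0
    grid_step: float = 0.5
    trial_budget: int = 1500
    fit_budget: int = 300
    n_restarts: int = 10
    n_perm: int = 1000
    cv_k: int = 3
    cv_iterations: int = 5
    observers_per_group: int = 7
    trials_per_direction: int = 60
    fit_grid_step: float = 1.0
    out_dir: str = "poplearn_out"
    data: str | None = None  # optional path to an existing trial table
    variants: tuple = ("full", "no_GC", "no_BA", "no_CI")
    fit_observers: int = 1  # observers to fit/compare in the pipeline
    stats_group: str = "est_train"

    def __post_init__(self):
        for name in (
            "trial_budget",
            "fit_budget",
            "n_restarts",
            "n_perm",
            "cv_k",
            "cv_iterations",
            "observers_per_group",
            "trials_per_direction",
            "fit_observers",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variants"] = list(self.variants)
        return d

    def digest(self) -> str:
        """Hash of the scientific configuration (paths excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("data", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON mapping."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    if "variants" in data:
        data["variants"] = tuple(data["variants"])
    return RunConfig(**data)
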