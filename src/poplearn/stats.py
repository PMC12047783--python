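"""Nonparametric behavioral statistics on trial tables.

Implements the study-specific analysis toolkit: sign-collapsing of
upward/downward trials, discrimination and signed-estimation accuracy,
AUROC with label-permutation tests and two-stage (Benjamini–Krieger–
Yekutieli) FDR control, cluster-mass permutation tests whose per-bin
statistic is the Wald z of a Poisson mixed model, and Gaussian-mixture
modality classification of estimate distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, pearsonr
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .grid import CW, CCW
from .simulate import TASK_DISC, TASK_EST
from .glmm import fit_poisson_glmm
from ._rng import as_rng

__all__ = [
    "collapse_by_category",
    "accuracy_metrics",
    "auroc",
    "auroc_permutation_test",
    "bky_fdr",
    "BinnedCounts",
    "bin_estimate_counts",
    "glmm_bin_zscores",
    "ClusterResult",
    "cluster_mass_test",
    "gmm_modality",
    "summarize_study",
    "auroc_table",
]

logger = logging.getLogger(__name__)

_FLIP = {CW: CCW, CCW: CW}


# ---------------------------------------------------------------------------
# collapsing and accuracy


def collapse_by_category(trials: pd.DataFrame) -> pd.DataFrame:
    """Merge downward trials into upward ones by negation.

    For rows with stimulus < 0 the stimulus is negated, estimation
    responses are negated, and discrimination responses are relabeled so
    correctness is preserved; afterwards every stimulus is positive and a
    positive estimate means "correct side of the boundary".
    """
    out = trials.copy()
    down = out["stimulus_deg"].to_numpy() < 0
    est_rows = out["task"].to_numpy() == TASK_EST
    disc_rows = out["task"].to_numpy() == TASK_DISC

    flip_est = down & est_rows
    resp = out["response"].to_numpy(dtype=object).copy()
    resp[flip_est] = [-float(v) for v in resp[flip_est]]
    flip_disc = down & disc_rows
    resp[flip_disc] = [_FLIP[v] for v in resp[flip_disc]]
    out["response"] = resp
    out["category"] = np.where(down, out["category"].map(_FLIP), out["category"])
    out["stimulus_deg"] = np.abs(out["stimulus_deg"])
    return out


def accuracy_metrics(collapsed: pd.DataFrame) -> pd.DataFrame:
    """Per observer × session × direction accuracy table.

    ``disc_accuracy`` is the fraction of correct discrimination choices;
    ``signed_est_accuracy`` the fraction of estimates on the correct
    (positive) side of the boundary.  Estimates exactly at 0° belong to
    neither category and are excluded.  Cells without trials are NaN.
    """
    rows = []
    for (obs, group, session, mag), cell in collapsed.groupby(
        ["observer_id", "group", "session", "stimulus_deg"], sort=True
    ):
        disc = cell[cell["task"] == TASK_DISC]
        est = cell[cell["task"] == TASK_EST]
        disc_acc = np.nan
        if len(disc):
            disc_acc = float(
                (disc["response"].to_numpy() == disc["category"].to_numpy()).mean()
            )
        est_acc = np.nan
        n_est = 0
        if len(est):
            vals = est["response"].to_numpy(dtype=float)
            vals = vals[vals != 0.0]
            n_est = vals.size
            if n_est:
                est_acc = float((vals > 0).mean())
        rows.append(
            {
                "observer_id": obs,
                "group": group,
                "session": session,
                "stimulus_deg": mag,
                "disc_accuracy": disc_acc,
                "n_disc": int(len(disc)),
                "signed_est_accuracy": est_acc,
                "n_est": n_est,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# AUROC


def auroc(pre_est, post_est) -> float:
    """Rank-based AUROC: P(post > pre) with ties counted 1/2.

    0.5 means complete overlap; 1 means every post estimate exceeds
    every pre estimate (a shift away from the boundary).
    """
    pre = np.asarray(pre_est, dtype=float)
    post = np.asarray(post_est, dtype=float)
    if pre.size == 0 or post.size == 0:
        raise ValueError("auroc requires nonempty samples")
    ranks = rankdata(np.concatenate([pre, post]))
    m = post.size
    r_post = ranks[pre.size :].sum()
    return float((r_post - m * (m + 1) / 2.0) / (pre.size * m))


def auroc_permutation_test(pre_est, post_est, n_perm: int = 1000, rng=None):
    """Two-tailed label-permutation test of AUROC against 0.5.

    Pre/post labels are shuffled ``n_perm`` times preserving group sizes;
    the p-value is the fraction of permuted |AUROC − 0.5| at least as
    large as observed, with the (b+1)/(n+1) small-sample correction.
    Returns ``(auroc_value, p_value)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = as_rng(rng)
    pre = np.asarray(pre_est, dtype=float)
    post = np.asarray(post_est, dtype=float)
    obs = auroc(pre, post)
    n, m = pre.size, post.size
    ranks = rankdata(np.concatenate([pre, post]))
    # each permutation re-assigns m pooled values to "post"; its AUROC is a
    # rank sum, so all permutations reduce to row-sums over shuffled ranks
    order = np.argsort(rng.random((n_perm, n + m)), axis=1)
    r_post = ranks[order[:, :m]].sum(axis=1)
    null = (r_post - m * (m + 1) / 2.0) / (n * m)
    b = int(np.sum(np.abs(null - 0.5) >= abs(obs - 0.5) - 1e-12))
    return obs, (b + 1.0) / (n_perm + 1.0)


def bky_fdr(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini–Krieger–Yekutieli two-stage adaptive FDR flags at level q."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, alpha=q, method="fdr_tsbky")[0]


def auroc_table(
    collapsed: pd.DataFrame, n_perm: int = 1000, q: float = 0.05, rng=None
) -> pd.DataFrame:
    """Per observer × direction AUROC between pre and post correct-side estimates.

    Only estimates on the correct (positive) side enter, so the measure
    is invariant to changes in signed estimation accuracy.  Permutation
    p-values are corrected with two-stage FDR across the whole table.
    """
    rng = as_rng(rng)
    est = collapsed[collapsed["task"] == TASK_EST]
    rows = []
    for (obs, group, mag), cell in est.groupby(
        ["observer_id", "group", "stimulus_deg"], sort=True
    ):
        vals = {
            s: cell.loc[cell["session"] == s, "response"].to_numpy(dtype=float)
            for s in ("pre", "post")
        }
        vals = {s: v[v > 0] for s, v in vals.items()}
        if vals["pre"].size == 0 or vals["post"].size == 0:
            continue
        a, p = auroc_permutation_test(vals["pre"], vals["post"], n_perm, rng)
        rows.append(
            {
                "observer_id": obs,
                "group": group,
                "stimulus_deg": mag,
                "auroc": a,
                "p_value": p,
                "n_pre": vals["pre"].size,
                "n_post": vals["post"].size,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["significant"] = bky_fdr(table["p_value"].to_numpy(), q)
    return table


# ---------------------------------------------------------------------------
# binning and the cluster-mass permutation test


@dataclass
class BinnedCounts:
    """Estimate counts per 5° bin × participant × session.

    ``counts`` has shape (n_subjects, 2, n_bins) with session order
    (pre, post); ``groups`` holds one group label per subject.
    """

    counts: np.ndarray
    bin_edges: np.ndarray
    subjects: list
    groups: np.ndarray
    n_dropped: int = 0

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]


def bin_estimate_counts(
    collapsed: pd.DataFrame,
    lo: float = -70.0,
    hi: float = 70.0,
    width: float = 5.0,
) -> BinnedCounts:
    """Bin collapsed estimates into 5° bins on [−70°, +70°].

    Bins are left-closed right-open, the last bin closed (numpy
    histogram convention).  Estimates outside the range are dropped and
    their number logged.
    """
    est = collapsed[collapsed["task"] == TASK_EST]
    edges = np.arange(lo, hi + width / 2.0, width)
    subjects = sorted(est["observer_id"].unique())
    groups = []
    counts = np.zeros((len(subjects), 2, edges.size - 1), dtype=int)
    dropped = 0
    for i, obs in enumerate(subjects):
        cell = est[est["observer_id"] == obs]
        groups.append(cell["group"].iloc[0])
        for j, session in enumerate(("pre", "post")):
            vals = cell.loc[cell["session"] == session, "response"].to_numpy(
                dtype=float
            )
            h, _ = np.histogram(vals, bins=edges)
            counts[i, j] = h
            dropped += int(vals.size - h.sum())
    if dropped:
        logger.info("bin_estimate_counts: dropped %d out-of-range estimates", dropped)
    return BinnedCounts(
        counts=counts,
        bin_edges=edges,
        subjects=subjects,
        groups=np.asarray(groups),
        n_dropped=dropped,
    )


def _session_design(n_subj: int) -> np.ndarray:
    X = np.zeros((n_subj, 2, 2))
    X[:, :, 0] = 1.0
    X[:, 1, 1] = 1.0
    return X


def _interaction_design(group_flags: np.ndarray) -> np.ndarray:
    S = group_flags.size
    X = np.zeros((S, 2, 4))
    X[:, :, 0] = 1.0
    X[:, :, 1] = group_flags[:, None]
    X[:, 1, 2] = 1.0
    X[:, 1, 3] = group_flags
    return X


def glmm_bin_zscores(
    counts: BinnedCounts, formula: str = "session", groups: tuple | None = None
) -> np.ndarray:
    """Per-bin Wald z from a Poisson mixed model.

    ``formula="session"`` fits counts ~ session + (1|subject) per bin and
    returns z for the session effect; ``formula="group-session"`` fits
    counts ~ group * session + (1|subject) for the two group labels in
    ``groups`` and returns z for the interaction.  All-zero bins give
    z = 0.
    """
    y = counts.counts.astype(float)  # (S, 2, n_bins)
    if formula == "session":
        X = _session_design(y.shape[0])
        coef = 1
    elif formula == "group-session":
        if groups is None:
            levels = list(dict.fromkeys(counts.groups))
            if len(levels) != 2:
                raise ValueError(
                    "group-session formula needs exactly two groups; "
                    f"found {levels!r} — pass groups=(g0, g1)"
                )
            groups = tuple(levels)
        keep = np.isin(counts.groups, groups)
        y = y[keep]
        flags = (counts.groups[keep] == groups[1]).astype(float)
        X = _interaction_design(flags)
        coef = 3
    else:
        raise ValueError(f"unknown formula {formula!r}")
    yb = np.moveaxis(y, 2, 0)  # (n_bins, S, 2)
    fit = fit_poisson_glmm(yb, X)
    return fit.z[:, coef]


@dataclass
class ClusterResult:
    """Outcome of a cluster-mass permutation test."""

    bin_edges: np.ndarray
    z: np.ndarray
    crit_lo: np.ndarray
    crit_hi: np.ndarray
    sig_bins: np.ndarray
    clusters: list = field(default_factory=list)
    null_max_mass: np.ndarray = field(default=None, repr=False)
    n_perm: int = 0

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c["p"] < alpha]


def _find_clusters(z: np.ndarray, sig: np.ndarray) -> list:
    """Maximal runs of adjacent significant bins with same-sign z."""
    clusters = []
    i = 0
    n = z.size
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        sign = np.sign(z[i])
        while j + 1 < n and sig[j + 1] and np.sign(z[j + 1]) == sign:
            j += 1
        clusters.append({"bins": list(range(i, j + 1)), "sign": int(sign),
                         "mass": float(z[i : j + 1].sum())})
        i = j + 1
    return clusters


def _within_subject_swaps(S: int, n_perm: int, rng) -> np.ndarray:
    return rng.random((n_perm, S)) < 0.5


def cluster_mass_test(
    counts: BinnedCounts,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng=None,
    design: str = "within-group",
    groups: tuple | None = None,
    pooled_critical: bool = False,
) -> ClusterResult:
    """Cluster-mass permutation test on binned estimate counts.

    Step 1 marks bins whose GLMM z falls outside the two-tailed
    critical values of that bin's own permutation distribution (or of
    all bins pooled, with ``pooled_critical``).  Step 2 groups adjacent
    significant same-sign bins into clusters, scores each by its summed
    z, and compares |mass| against the permutation distribution of the
    largest |mass| per permuted dataset.  Pre/post labels are swapped
    within (never across) participants, jointly for all bins; the
    interaction design additionally permutes group assignments.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = as_rng(rng)
    y = counts.counts.astype(float)  # (S, 2, n_bins)
    group_flags = None
    if design == "within-group":
        formula_X = _session_design(y.shape[0])
        coef = 1
    elif design == "group-interaction":
        if groups is None:
            levels = list(dict.fromkeys(counts.groups))
            if len(levels) != 2:
                raise ValueError(
                    "group-interaction design needs exactly two groups; "
                    f"found {levels!r} — pass groups=(g0, g1)"
                )
            groups = tuple(levels)
        keep = np.isin(counts.groups, groups)
        y = y[keep]
        group_flags = (counts.groups[keep] == groups[1]).astype(float)
        formula_X = _interaction_design(group_flags)
        coef = 3
    else:
        raise ValueError(f"unknown design {design!r}")

    S, _, n_bins = y.shape
    swaps = _within_subject_swaps(S, n_perm, rng)
    perms = np.empty((n_perm + 1, S, 2, n_bins))
    perms[0] = y
    for p in range(n_perm):
        yp = y
        if group_flags is not None:
            # permuting group assignments == permuting subject rows under a
            # fixed design, since the random intercept is exchangeable
            yp = y[rng.permutation(S)]
        yp = yp.copy()
        flip = swaps[p]
        yp[flip] = yp[flip][:, ::-1]
        perms[p + 1] = yp

    yb = np.moveaxis(perms, 3, 1).reshape((n_perm + 1) * n_bins, S, 2)
    fit = fit_poisson_glmm(yb, formula_X)
    zall = fit.z[:, coef].reshape(n_perm + 1, n_bins)
    z_obs = zall[0]
    z_null = zall[1:]

    if pooled_critical:
        lo = np.quantile(z_null, alpha / 2.0)
        hi = np.quantile(z_null, 1.0 - alpha / 2.0)
        crit_lo = np.full(n_bins, lo)
        crit_hi = np.full(n_bins, hi)
    else:
        crit_lo = np.quantile(z_null, alpha / 2.0, axis=0)
        crit_hi = np.quantile(z_null, 1.0 - alpha / 2.0, axis=0)

    def sig_mask(z):
        return (z < crit_lo) | (z > crit_hi)

    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        cl = _find_clusters(z_null[p], sig_mask(z_null[p]))
        if cl:
            null_max[p] = max(abs(c["mass"]) for c in cl)

    sig = sig_mask(z_obs)
    clusters = _find_clusters(z_obs, sig)
    for c in clusters:
        b = int(np.sum(null_max >= abs(c["mass"]) - 1e-12))
        c["p"] = (b + 1.0) / (n_perm + 1.0)
        c["sig_05"] = c["p"] < 0.05
        c["sig_10"] = c["p"] < 0.10
        c["edges"] = (
            float(counts.bin_edges[c["bins"][0]]),
            float(counts.bin_edges[c["bins"][-1] + 1]),
        )
    return ClusterResult(
        bin_edges=counts.bin_edges,
        z=z_obs,
        crit_lo=crit_lo,
        crit_hi=crit_hi,
        sig_bins=sig,
        clusters=clusters,
        null_max_mass=null_max,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# modality and study summary


_MODALITY_LABELS = {1: "unimodal", 2: "bimodal", 3: "trimodal"}


def gmm_modality(est, k_max: int = 3, seed: int = 0) -> tuple[int, str]:
    """Classify an estimate distribution's modality via GMM + BIC.

    Fits Gaussian mixtures with 1..k_max components (10 restarts each)
    and returns the BIC-selected component count with its label.
    """
    x = np.asarray(est, dtype=float).reshape(-1, 1)
    if x.shape[0] < 10:
        raise ValueError(f"need at least 10 estimates, got {x.shape[0]}")
    best_k, best_bic = 1, np.inf
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k, n_init=10, random_state=seed, reg_covar=1e-4
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic - 1e-9:
            best_k, best_bic = k, bic
    label = _MODALITY_LABELS.get(best_k, f"{best_k}-modal")
    return best_k, label


def summarize_study(trials: pd.DataFrame, n_perm: int = 1000, rng=None) -> dict:
    """Assemble the study-level summary tables.

    Returns a dict with ``accuracy`` (per observer × session ×
    direction), ``group_accuracy`` (group means), ``auroc`` (per
    observer × direction with permutation p and FDR flags), and
    ``correlation`` (Pearson r between signed estimation accuracy and
    discrimination accuracy across observer × direction × session
    cells; NaN when degenerate).
    """
    rng = as_rng(rng)
    collapsed = collapse_by_category(trials)
    acc = accuracy_metrics(collapsed)
    group_acc = (
        acc.groupby(["group", "session", "stimulus_deg"])[
            ["disc_accuracy", "signed_est_accuracy"]
        ]
        .mean()
        .reset_index()
    )
    atab = auroc_table(collapsed, n_perm=n_perm, rng=rng)

    cells = acc.dropna(subset=["disc_accuracy", "signed_est_accuracy"])
    r = p = np.nan
    if len(cells) >= 3:
        x = cells["disc_accuracy"].to_numpy()
        y = cells["signed_est_accuracy"].to_numpy()
        if np.std(x) > 0 and np.std(y) > 0:
            r, p = pearsonr(x, y)
    correlation = pd.DataFrame(
        [{"r": r, "p_value": p, "n_cells": len(cells)}]
    )
    return {
        "accuracy": acc,
        "group_accuracy": group_acc,
        "auroc": atab,
        "correlation": correlation,
    }
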