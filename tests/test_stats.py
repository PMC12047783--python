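"""Collapsing, accuracy metrics, AUROC + FDR, binning, clusters, modality."""

import numpy as np
import pandas as pd
import pytest

import poplearn as pl
from poplearn.stats import (
    collapse_by_category,
    accuracy_metrics,
    auroc,
    auroc_permutation_test,
    bky_fdr,
    bin_estimate_counts,
    cluster_mass_test,
    gmm_modality,
    summarize_study,
)


def trial_row(stim, task, response, session="pre", obs="o1", group="est_train"):
    return {
        "observer_id": obs,
        "group": group,
        "session": session,
        "task": task,
        "stimulus_deg": stim,
        "category": pl.CW if stim > 0 else pl.CCW,
        "response": response,
        "trial_index": 0,
        "seed": 0,
    }


class TestCollapse:
    def test_downward_estimates_are_negated(self):
        t = pd.DataFrame([trial_row(-4.0, "est", -12.0), trial_row(-4.0, "est", 5.0)])
        c = collapse_by_category(t)
        assert list(c["stimulus_deg"]) == [4.0, 4.0]
        assert list(c["response"]) == [12.0, -5.0]  # misclassified stays negative
        assert set(c["category"]) == {pl.CW}

    def test_upward_trials_unchanged(self):
        t = pd.DataFrame([trial_row(8.0, "est", 20.0), trial_row(8.0, "disc", pl.CW)])
        c = collapse_by_category(t)
        assert list(c["response"]) == [20.0, pl.CW]
        assert list(c["stimulus_deg"]) == [8.0, 8.0]

    def test_discrimination_correctness_preserved(self):
        t = pd.DataFrame(
            [trial_row(-4.0, "disc", pl.CCW), trial_row(-4.0, "disc", pl.CW)]
        )
        c = collapse_by_category(t)
        # correct stays correct, wrong stays wrong
        assert c.iloc[0]["response"] == c.iloc[0]["category"]
        assert c.iloc[1]["response"] != c.iloc[1]["category"]

    def test_negation_is_an_involution_on_downward_trials(self):
        t = pd.DataFrame([trial_row(-4.0, "est", -12.0), trial_row(-2.0, "disc", pl.CW)])
        once = collapse_by_category(t)
        # mirror the collapsed table back down and collapse again
        mirrored = once.copy()
        mirrored["stimulus_deg"] = -mirrored["stimulus_deg"]
        mirrored["category"] = mirrored["category"].map({pl.CW: pl.CCW, pl.CCW: pl.CW})
        est = mirrored["task"] == "est"
        mirrored.loc[est, "response"] = -mirrored.loc[est, "response"].astype(float)
        mirrored.loc[~est, "response"] = mirrored.loc[~est, "response"].map(
            {pl.CW: pl.CCW, pl.CCW: pl.CW}
        )
        twice = collapse_by_category(mirrored)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )


class TestAccuracy:
    def test_counts_positive_estimates(self):
        rows = [trial_row(4.0, "est", v) for v in (12.0, 9.0, -5.0, 14.0)]
        acc = accuracy_metrics(pd.DataFrame(rows))
        assert acc.iloc[0]["signed_est_accuracy"] == pytest.approx(0.75)

    def test_all_positive_and_all_negative(self):
        up = accuracy_metrics(pd.DataFrame([trial_row(4.0, "est", v) for v in (1.0, 2.0)]))
        dn = accuracy_metrics(pd.DataFrame([trial_row(4.0, "est", v) for v in (-1.0, -2.0)]))
        assert up.iloc[0]["signed_est_accuracy"] == 1.0
        assert dn.iloc[0]["signed_est_accuracy"] == 0.0

    def test_boundary_estimates_are_excluded(self):
        acc = accuracy_metrics(
            pd.DataFrame([trial_row(4.0, "est", v) for v in (0.0, 3.0, -3.0)])
        )
        assert acc.iloc[0]["signed_est_accuracy"] == pytest.approx(0.5)
        assert acc.iloc[0]["n_est"] == 2

    def test_empty_cell_is_nan_not_zero(self):
        acc = accuracy_metrics(pd.DataFrame([trial_row(4.0, "est", 5.0)]))
        assert np.isnan(acc.iloc[0]["disc_accuracy"])


class TestAuroc:
    def test_identical_samples_give_half(self):
        x = np.array([3.0, 9.0, 15.0, 15.0])
        assert auroc(x, x) == 0.5

    def test_complete_separation(self):
        assert auroc([1, 2, 3], [4, 5, 6]) == 1.0
        assert auroc([4, 5, 6], [1, 2, 3]) == 0.0

    def test_interleaved_example(self):
        assert auroc([1, 3], [2, 4]) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_pair_oracle_small_n(self, seed):
        """For all sample sizes up to 6 (ties included), AUROC equals the
        fraction of (pre, post) pairs with post > pre plus half the ties."""
        rng = np.random.default_rng(seed)
        n, m = rng.integers(1, 7, size=2)
        pre = rng.integers(0, 5, size=n).astype(float)
        post = rng.integers(0, 5, size=m).astype(float)
        oracle = np.mean(
            [(q > p) + 0.5 * (q == p) for p in pre for q in post]
        )
        assert auroc(pre, post) == pytest.approx(oracle, rel=1e-12)

    def test_permutation_test_detects_large_shift(self):
        rng = np.random.default_rng(0)
        hits = 0
        for s in range(20):
            pre = rng.normal(10, 3, 30)
            post = pre + 10.0
            _, p = auroc_permutation_test(pre, post, n_perm=200, rng=np.random.default_rng(s))
            hits += p < 0.01
        assert hits >= 19

    def test_permutation_p_never_zero(self):
        pre = np.zeros(20)
        post = np.ones(20)
        _, p = auroc_permutation_test(pre, post, n_perm=200, rng=np.random.default_rng(1))
        assert p >= 1.0 / 201.0

    def test_rejects_tiny_n_perm(self):
        with pytest.raises(ValueError):
            auroc_permutation_test([1.0], [2.0], n_perm=10)


def reference_bky(pvals, q):
    """Independently coded two-stage BKY step-up (definition 6 of the
    original procedure), used as an oracle."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    q1 = q / (1.0 + q)
    # stage 1: BH at level q'
    r1 = _bh_count(p, q1)
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    m0 = m - r1
    # stage 2: BH at level q' * m / m0
    r2 = _bh_count(p, q1 * m / m0)
    thresh = np.sort(p)[r2 - 1] if r2 > 0 else -1.0
    return p <= thresh


def _bh_count(p, q):
    ps = np.sort(p)
    m = p.size
    ok = ps <= q * np.arange(1, m + 1) / m
    return int(np.max(np.nonzero(ok)[0]) + 1) if ok.any() else 0


class TestBkyFdr:
    def test_all_ones_reject_nothing(self):
        assert not bky_fdr(np.ones(8)).any()

    def test_single_small_p_is_flagged(self):
        assert bky_fdr(np.array([0.001])).all()

    def test_matches_independent_reference_on_fixed_vector(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216])
        np.testing.assert_array_equal(bky_fdr(p, 0.05), reference_bky(p, 0.05))

    @pytest.mark.parametrize("seed", range(10))
    def test_reference_agreement_monotonicity_and_bh_dominance(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = np.round(rng.beta(0.3, 1.0, size=12), 4)
        flags = bky_fdr(p, 0.05)
        np.testing.assert_array_equal(flags, reference_bky(p, 0.05))
        # monotone in p
        order = np.argsort(p)
        f = flags[order]
        assert not np.any(~f[:-1] & f[1:])
        # at least as many discoveries as plain BH at the same level
        bh = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        assert flags.sum() >= bh.sum()

    def test_rejects_invalid_pvalues(self):
        with pytest.raises(ValueError):
            bky_fdr(np.array([0.5, 1.2]))


class TestBinning:
    def test_28_bins_spanning_pm70(self, small_study):
        trials, _ = small_study
        counts = bin_estimate_counts(collapse_by_category(trials))
        assert counts.n_bins == 28
        assert counts.bin_edges[0] == -70.0 and counts.bin_edges[-1] == 70.0

    def test_bin_rule_left_closed(self):
        t = pd.DataFrame([trial_row(4.0, "est", 12.3), trial_row(4.0, "est", 10.0)])
        counts = bin_estimate_counts(collapse_by_category(t))
        bin_10_15 = np.searchsorted(counts.bin_edges, 10.0, side="right") - 1
        assert counts.counts[0, 0, bin_10_15] == 2

    def test_counts_conserved_and_drops_logged(self):
        vals = [3.0, -12.0, 69.9, 70.0, 71.0, -80.0]
        t = pd.DataFrame([trial_row(4.0, "est", v) for v in vals])
        counts = bin_estimate_counts(collapse_by_category(t))
        # 70.0 falls in the closed last bin; 71 and -80 are dropped
        assert counts.counts.sum() == 4
        assert counts.n_dropped == 2


class TestClusterMass:
    def test_injected_shift_produces_signed_clusters(self):
        """Moving 30% of post estimates from a negative mode to +15° yields a
        significant positive cluster there and a negative one at the vacated
        location."""
        rng = np.random.default_rng(5)
        frames = []
        for i in range(7):
            pre = pl.generate_mixture_estimates(
                pl.MixtureSpec(mu_pos=15.0, mu_neg=-9.0, sigma=2.5, w_neg=0.35), 120, rng
            )
            post = pl.generate_mixture_estimates(
                pl.MixtureSpec(mu_pos=15.0, mu_neg=-9.0, sigma=2.5, w_neg=0.05), 120, rng
            )
            for session, vals in (("pre", pre), ("post", post)):
                frames.append(
                    pd.DataFrame(
                        [trial_row(4.0, "est", v, session=session, obs=f"s{i}") for v in vals]
                    )
                )
        counts = bin_estimate_counts(collapse_by_category(pd.concat(frames)))
        res = cluster_mass_test(counts, n_perm=200, rng=np.random.default_rng(6))
        sig = res.significant(0.05)
        assert any(c["sign"] > 0 and c["edges"][0] >= 5 and c["edges"][1] <= 25 for c in sig)
        assert any(c["sign"] < 0 and c["edges"][0] >= -20 and c["edges"][1] <= 0 for c in sig)

    def test_requires_enough_permutations(self, small_study):
        trials, _ = small_study
        counts = bin_estimate_counts(collapse_by_category(trials))
        with pytest.raises(ValueError):
            cluster_mass_test(counts, n_perm=10)


class TestModality:
    def test_single_gaussian_is_unimodal(self):
        x = np.random.default_rng(0).normal(12, 3, 200)
        k, label = gmm_modality(x, seed=0)
        assert (k, label) == (1, "unimodal")

    def test_two_mode_mixture_is_bimodal(self):
        rng = np.random.default_rng(1)
        x = pl.generate_mixture_estimates(
            pl.MixtureSpec(mu_pos=15.0, mu_neg=-9.0, sigma=3.0, w_neg=0.3), 200, rng
        )
        k, label = gmm_modality(x, seed=0)
        assert (k, label) == (2, "bimodal")

    def test_three_modes_detected(self):
        rng = np.random.default_rng(2)
        comp = rng.integers(0, 3, 300)
        x = rng.normal(np.array([-12.0, 0.0, 14.0])[comp], 2.0)
        k, _ = gmm_modality(x, seed=0)
        assert k == 3

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            gmm_modality(np.arange(5.0))


class TestSummarizeStudy:
    def test_model_cohort_shows_accuracy_coupling(self, full_study):
        """Signed estimation accuracy correlates with discrimination accuracy
        across observers and directions (r > 0.4)."""
        trials, _ = full_study
        out = summarize_study(trials, n_perm=150, rng=np.random.default_rng(3))
        assert out["correlation"].iloc[0]["r"] > 0.4
        assert {"accuracy", "group_accuracy", "auroc", "correlation"} <= set(out)
        assert len(out["auroc"]) > 0 and out["auroc"]["auroc"].between(0, 1).all()

    def test_constant_accuracy_gives_missing_correlation(self):
        rows = [
            trial_row(4.0, "est", 5.0, obs=o, session=s)
            for o in ("a", "b", "c")
            for s in ("pre", "post")
        ] + [
            trial_row(4.0, "disc", pl.CW, obs=o, session=s)
            for o in ("a", "b", "c")
            for s in ("pre", "post")
        ]
        out = summarize_study(pd.DataFrame(rows), n_perm=150)
        assert np.isnan(out["correlation"].iloc[0]["r"])

    def test_control_group_stable_pre_to_post(self, full_study):
        """Without a training effect, control accuracy changes stay within
        3 binomial SE."""
        trials, _ = full_study
        acc = accuracy_metrics(collapse_by_category(trials))
        ctl = acc[acc["group"] == "control"]
        pre = ctl[ctl["session"] == "pre"]
        post = ctl[ctl["session"] == "post"]
        p1 = pre["disc_accuracy"].mean()
        p2 = post["disc_accuracy"].mean()
        n = pre["n_disc"].sum()
        se = np.sqrt(p1 * (1 - p1) / n + p2 * (1 - p2) / n)
        assert abs(p2 - p1) < 3 * se
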