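"""Energy distance, behavioral loss, weight normalization, variants, fitting."""

import numpy as np
import pytest
import scipy.stats

import poplearn as pl
from poplearn.loss import (
    LossSpec,
    ObserverData,
    energy_distance,
    behavioral_loss,
    compute_loss_weights,
    loss_terms,
    simulate_model_behavior,
)
from poplearn.variants import make_variant, VARIANT_NAMES
from poplearn.fitting import fit_observer
from poplearn._rng import child_seed


class TestEnergyDistance:
    def test_identical_multisets_give_zero(self):
        x = np.array([1.0, 2.0, 2.0, 5.0])
        assert energy_distance(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_point_masses(self):
        assert energy_distance([0.0], [1.0]) == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 5, 40)
        y = rng.normal(2, 3, 40)
        ours = energy_distance(x, y)
        oracle = (
            2 * np.abs(x[:, None] - y[None, :]).mean()
            - np.abs(x[:, None] - x[None, :]).mean()
            - np.abs(y[:, None] - y[None, :]).mean()
        )
        assert ours == pytest.approx(oracle, rel=1e-12)

    def test_agrees_with_scipy_energy_distance(self):
        """scipy reports the square root of the same statistic (in the
        large-sample/U-vs-V limit they coincide on equal-size samples)."""
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 500), rng.normal(1, 2, 500)
        ours = energy_distance(x, y)
        assert scipy.stats.energy_distance(x, y) ** 2 == pytest.approx(ours, rel=0.02)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            energy_distance([], [1.0])


@pytest.fixture(scope="module")
def demo_data(observer_trials):
    return ObserverData.from_trials(observer_trials)


@pytest.fixture(scope="module")
def spec():
    return LossSpec(trial_budget=400, grid_step=2.0)


class TestBehavioralLoss:
    def test_seeded_evaluations_are_bit_identical(self, demo_data, demo_observer, spec):
        a = behavioral_loss(demo_data, demo_observer, spec, seed=5)
        b = behavioral_loss(demo_data, demo_observer, spec, seed=5)
        c = behavioral_loss(demo_data, demo_observer, spec, seed=6)
        assert a == b
        assert a != c
        assert a >= 0

    def test_zero_disc_weight_reduces_to_energy_sum(self, demo_data, demo_observer):
        sp = LossSpec(w_disc=0.0, w_est=1.0, trial_budget=400, grid_step=2.0)
        loss = behavioral_loss(demo_data, demo_observer, sp, seed=7)
        model = simulate_model_behavior(demo_observer, sp, seed=7)
        manual = sum(
            energy_distance(demo_data.estimates[k], model.estimates[k])
            for k in demo_data.estimates
        )
        assert loss == pytest.approx(manual, rel=1e-12)

    def test_l1_term_is_zero_on_self_simulated_accuracies(self, demo_observer, spec):
        """Data whose accuracies equal the model's own simulation (same seed)
        has an exactly zero discrimination term."""
        model = simulate_model_behavior(demo_observer, spec, seed=11)
        data = ObserverData(
            disc_acc=dict(model.disc_acc),
            disc_n={k: spec.trial_budget for k in model.disc_acc},
            estimates={k: v.copy() for k, v in model.estimates.items()},
        )
        t_disc, t_est = loss_terms(data, demo_observer, spec, seed=11)
        assert t_disc == 0.0
        assert t_est == pytest.approx(0.0, abs=1e-12)

    def test_noise_floor_shrinks_with_trial_budget(self, demo_data, demo_observer):
        sds = []
        for budget in (200, 800, 3200):
            sp = LossSpec(trial_budget=budget, grid_step=2.0)
            losses = [
                behavioral_loss(demo_data, demo_observer, sp, seed=s) for s in range(6)
            ]
            sds.append(np.std(losses))
        assert sds[2] < sds[0]

    def test_missing_condition_raises(self, observer_trials):
        partial = observer_trials[observer_trials["session"] == "pre"]
        with pytest.raises(ValueError, match="session 'post'|post"):
            ObserverData.from_trials(partial)


class TestLossWeights:
    def test_weighted_terms_are_one_at_init(self, demo_data, demo_observer, spec):
        w_disc, w_est = compute_loss_weights(demo_data, demo_observer, spec, seed=13)
        t_disc, t_est = loss_terms(demo_data, demo_observer, spec, seed=13)
        assert w_disc * t_disc == pytest.approx(1.0)
        assert w_est * t_est == pytest.approx(1.0)

    def test_zero_term_falls_back_with_warning(self, demo_observer, spec):
        model = simulate_model_behavior(demo_observer, spec, seed=17)
        data = ObserverData(
            disc_acc=dict(model.disc_acc),
            disc_n={k: spec.trial_budget for k in model.disc_acc},
            estimates={k: v.copy() for k, v in model.estimates.items()},
        )
        with pytest.warns(UserWarning, match="zero"):
            w_disc, _ = compute_loss_weights(data, demo_observer, spec, seed=17)
        assert w_disc == 1.0


class TestVariants:
    def test_unknown_name_lists_valid_ones(self):
        with pytest.raises(ValueError, match="full"):
            make_variant("bogus")

    def test_full_model_has_six_free_parameters(self):
        assert make_variant("full").n_free == 6

    def test_no_gc_ties_gains(self):
        v = make_variant("no_GC")
        p = v.build_params(np.array([0.3, 20.0, 3.0, 8.0, 0.02]))
        assert p.g_post == p.g_pre

    def test_no_ba_has_identity_warp(self):
        v = make_variant("no_BA")
        p = v.build_params(np.array([8.0, 10.0, 0.02]))
        assert p.warp is None and p.g_post == 18.0

    def test_no_ci_disables_conditioning_only(self):
        v = make_variant("no_CI")
        assert not v.conditional and v.n_free == 6

    def test_tc_builds_density_bumps(self):
        v = make_variant("TC")
        p = v.build_params(np.array([0.3, 20.0, 3.0, 8.0, 0.02, 300.0, 5.0]))
        assert p.tuning_change.amplitude == 300.0
        assert p.tuning_change.sigma == 5.0
        assert p.g_post == p.g_pre
        r = make_variant("TC_reduced").build_params(
            np.array([0.3, 20.0, 3.0, 8.0, 0.02, 300.0])
        )
        assert r.tuning_change.sigma == 4.0

    def test_all_variants_build_within_bounds(self):
        for name in VARIANT_NAMES:
            v = make_variant(name)
            lo, hi = np.array(v.bounds).T
            mid = 0.5 * (lo + hi)
            p = v.build_params(mid)
            assert p.g_post >= p.g_pre


def test_fit_is_deterministic_and_best_of_restarts(demo_data, spec):
    fit = fit_observer(demo_data, "no_BA", spec=spec, n_restarts=2, budget=40, seed=3)
    fit2 = fit_observer(demo_data, "no_BA", spec=spec, n_restarts=2, budget=40, seed=3)
    assert fit.best_loss == fit2.best_loss
    assert fit.best_loss == min(fit.restart_losses)
    assert len(fit.restart_losses) == 2
    d = fit.to_dict()
    assert d["variant"] == "no_BA" and set(d["best_x"]) == {"g_pre", "dg", "lapse"}


def test_full_model_nests_reduced_model(grid_half):
    """On data generated without a gain change, the full model's fitted loss
    is no worse than no_GC's beyond optimizer noise (nesting)."""
    import pandas as pd

    gen = pl.ObserverParams(
        g_pre=8.0, g_post=8.0, lapse=0.02, warp=pl.WarpSpec(a=0.5, w_b=20, sigma_b=3)
    )
    frames = []
    for session in ("pre", "post"):
        for task in ("disc", "est"):
            t, _ = pl.simulate_block(
                gen, session, task, [-8, -4, -2, 2, 4, 8], 25,
                seed=child_seed(50, f"{session}{task}"), grid=pl.DirectionGrid(1.0),
            )
            frames.append(t)
    data = ObserverData.from_trials(pd.concat(frames, ignore_index=True))
    sp = LossSpec(trial_budget=300, grid_step=2.0)
    kw = dict(spec=sp, n_restarts=1, budget=60, seed=2)
    full = fit_observer(data, "full", **kw)
    red = fit_observer(data, "no_GC", weights=full.weights, **kw)
    assert full.best_loss <= red.best_loss + 0.35
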