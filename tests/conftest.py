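import numpy as np
import pytest

import poplearn as pl


@pytest.fixture(scope="session")
def grid_half():
    """0.5° decoding grid: fine enough for behavioral checks, fast."""
    return pl.DirectionGrid(0.5)


@pytest.fixture(scope="session")
def demo_observer():
    """A strongly warped, clearly learning observer used across tests."""
    return pl.ObserverParams(
        g_pre=8.0,
        g_post=24.0,
        lapse=0.02,
        warp=pl.WarpSpec(a=0.3, w_b=20.0, sigma_b=3.0),
        shared=pl.SharedParams(),
    )


@pytest.fixture(scope="session")
def small_study():
    """Reduced synthetic study: 3 observers/group, 20 trials/direction."""
    design = pl.StudyDesign(
        observers_per_group={g: 3 for g in ("control", "disc_train", "est_train")},
        trials_per_direction=20,
    )
    trials, sidecar = pl.generate_study(design, seed=7, grid_step=1.0)
    return trials, sidecar


@pytest.fixture(scope="session")
def full_study():
    """Default-size synthetic study (7 observers/group, 60 trials/direction)."""
    trials, sidecar = pl.generate_study(seed=3)
    return trials, sidecar


@pytest.fixture(scope="session")
def observer_trials(demo_observer):
    """Trial table for one observer simulated from the demo parameters."""
    import pandas as pd

    frames = []
    g = pl.DirectionGrid(1.0)
    for session in ("pre", "post"):
        for task in ("disc", "est"):
            t, _ = pl.simulate_block(
                demo_observer,
                session,
                task,
                [-8.0, -4.0, -2.0, 2.0, 4.0, 8.0],
                30,
                seed=1000 + hash((session, task)) % 1000,
                grid=g,
                observer_id="demo",
                group="est_train",
            )
            frames.append(t)
    return pd.concat(frames, ignore_index=True)
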