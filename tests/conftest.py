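"""Shared fixtures: compressed-schedule simulations reused across tests.

Simulated cohorts use a compressed inter-trial interval (160 s instead of
the 20-min protocol value). The ζ statistics only require ~120 s of
pre-onset coverage per trial and are invariant to the interval length, so
this keeps the suite fast without changing what is being tested.
"""

from __future__ import annotations

import numpy as np
import pytest

import zetafish as zf
from zetafish.config import ExperimentConfig
from zetafish.pipeline import compute_panels, score_cohort

ITI_S = 160.0


@pytest.fixture(scope="session")
def geometry():
    return zf.TankGeometry()


@pytest.fixture(scope="session")
def config():
    return ExperimentConfig()


def make_cohort(n_fish, scenario="learning", seed=0, n_days=2, tpds=9, food_delay_s=30.0,
                model=None, geometry=None):
    geometry = geometry or zf.TankGeometry()
    model = model or zf.BehaviorModel()
    return zf.simulate_cohort(
        n_fish,
        geometry,
        model,
        scenario=scenario,
        seed=seed,
        n_days=n_days,
        trials_per_day_per_stimulus=tpds,
        iti_s=ITI_S,
        first_onset_s=ITI_S,
        food_delay_s=food_delay_s,
    )


def cohort_scores(members, config, offset_s=0.0, weighted=False):
    panels = compute_panels(members, config)
    schedules = [m.schedule for m in members]
    return panels, schedules, score_cohort(
        panels, schedules, config.windows, offset_s=offset_s, weighted=weighted
    )


@pytest.fixture(scope="session")
def learning_cohort_12(config):
    """12 fish, 2 training days, default learning model."""
    members = make_cohort(12, scenario="learning", seed=11)
    panels, schedules, scores = cohort_scores(members, config)
    return members, panels, schedules, scores


@pytest.fixture(scope="session")
def random_trajectory(geometry):
    """Smooth random walk inside the tank for oracle comparisons."""
    rng = np.random.default_rng(123)
    n = 2000
    steps = rng.normal(0, 0.08, size=(n, 3)).cumsum(axis=0)
    lo = np.array([0.3, 0.3, 0.3])
    hi = np.array([geometry.length_cm, geometry.width_cm, geometry.water_height_cm]) - 0.3
    span = hi - lo
    pos = lo + np.abs((steps - lo) % (2 * span) - span)  # reflecting walls
    t = np.arange(n) / 30.0
    return zf.Trajectory(fish_id="rand", fps=30.0, t=t, pos=pos)
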