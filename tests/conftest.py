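"""Shared fixtures.

The expensive objects (a conditioned ORd cell, its steady-state AP, and
the two IVT surfaces used throughout the analysis tests) are session
scoped and lazily built.  Tests use 150 conditioning beats instead of the
protocol default of 1000; the end-diastolic state is converged to well
under the tolerances asserted anywhere in the suite (the slow ionic drift
beyond beat ~100 is < 0.1 mV in diastolic V_m).
"""

from __future__ import annotations

import numpy as np
import pytest

from ivtsurf.ivt_surface import build_surface, default_T_grid
from ivtsurf.models import ModelParams, ORdModel, ToyModel
from ivtsurf.protocols import StimulusSpec, condition, find_threshold_current, simulate_ap

N_BEATS_TEST = 150
BCL = 800.0


@pytest.fixture(scope="session")
def ord_model():
    return ORdModel(ModelParams())


@pytest.fixture(scope="session")
def ord_rest(ord_model):
    return condition(ord_model, BCL, N_BEATS_TEST)


@pytest.fixture(scope="session")
def ord_stim(ord_model, ord_rest):
    # the conditioning convention: 0.5 ms pulse, 50% above threshold
    thr = find_threshold_current(ord_rest, ord_model, duration=0.5)
    return StimulusSpec(amplitude=-1.5 * thr, duration=0.5)


@pytest.fixture(scope="session")
def ord_traj(ord_model, ord_rest, ord_stim):
    return simulate_ap(ord_rest, ord_model, ord_stim, duration=BCL)


@pytest.fixture(scope="session")
def ord_surf5(ord_traj):
    """Threshold-analysis surface: t_vc = 5 ms, full default grids."""
    return build_surface(ord_traj, T_grid=default_T_grid(ord_traj), t_vc=5.0)


@pytest.fixture(scope="session")
def ord_surf1(ord_traj):
    """Morphology/R_m surface: t_vc = 1 ms, full default grids."""
    return build_surface(ord_traj, T_grid=default_T_grid(ord_traj), t_vc=1.0)


@pytest.fixture(scope="session")
def toy_ohmic():
    return ToyModel(kind="ohmic")


@pytest.fixture(scope="session")
def toy_cubic():
    return ToyModel(kind="cubic")


@pytest.fixture(scope="session")
def toy_traj(toy_ohmic):
    return simulate_ap(toy_ohmic.initial_state(), toy_ohmic,
                       StimulusSpec(amplitude=0.0, duration=0.5), duration=120.0)
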