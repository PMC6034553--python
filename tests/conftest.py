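"""Shared fixtures: small deterministic cells and synthetic models.

Everything is generated programmatically; session scope keeps the
simulation-heavy fixtures to one build per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from humanl23.cable import PassiveParams, build_compartmental_model
from humanl23.morphology import Morphology, Section
from humanl23.synthetic import HUMAN_RECIPE, RAT_RECIPE, default_study_model


@pytest.fixture(scope="session")
def passive_params() -> PassiveParams:
    return PassiveParams()


def make_soma_only(r_m=20000.0, c_m=0.5, diam=20.0) -> Morphology:
    return Morphology(sections={
        1: Section(id=1, parent_id=None, type=1,
                   points=np.array([[0.0, 0.0, 0.0, diam]])),
    })


def make_ball_and_sticks(n_dend=2, length=150.0, diam=1.2, taper=0.9):
    """Soma plus ``n_dend`` straight basal dendrites."""
    secs = {1: Section(id=1, parent_id=None, type=1,
                       points=np.array([[0.0, 0.0, 0.0, 16.0]]))}
    for k in range(n_dend):
        ang = 2 * np.pi * k / max(n_dend, 1)
        end = [length * np.cos(ang), length * np.sin(ang), -60.0]
        secs[k + 2] = Section(
            id=k + 2, parent_id=1, type=3,
            points=np.array([[0.0, 0.0, 0.0, diam], [*end, diam * taper]]),
        )
    return Morphology(sections=secs)


def make_y_tree(stem=80.0, branch=120.0, d_stem=1.6, d_branch=1.0):
    """Soma, one basal stem, two daughter branches."""
    secs = {
        1: Section(id=1, parent_id=None, type=1,
                   points=np.array([[0.0, 0.0, 0.0, 16.0]])),
        2: Section(id=2, parent_id=1, type=3,
                   points=np.array([[0, 0, 0, d_stem], [0, 0, -stem, d_stem]])),
        3: Section(id=3, parent_id=2, type=3,
                   points=np.array([[0, 0, -stem, d_branch],
                                    [branch * 0.7, 0, -stem - branch * 0.7, d_branch]])),
        4: Section(id=4, parent_id=2, type=3,
                   points=np.array([[0, 0, -stem, d_branch],
                                    [-branch * 0.7, 0, -stem - branch * 0.7, d_branch]])),
    }
    return Morphology(sections=secs)


def make_star(n_arms=6, shaft=60.0, arm=220.0, d_shaft=2.0, d_arm=0.6,
              soma_d=40.0):
    """Shafts radiating thin, electrotonically long terminals from a large
    leaky soma — built to be mutually decoupled."""
    secs = {1: Section(id=1, parent_id=None, type=1,
                       points=np.array([[0.0, 0.0, 0.0, soma_d]]))}
    sid = 2
    for k in range(n_arms):
        ang = 2 * np.pi * k / n_arms
        ux, uy = np.cos(ang), np.sin(ang)
        p0 = [shaft * ux, shaft * uy, 0.0]
        secs[sid] = Section(id=sid, parent_id=1, type=3,
                            points=np.array([[0, 0, 0, d_shaft],
                                             [*p0, d_shaft]]))
        p1 = [(shaft + arm) * ux, (shaft + arm) * uy, 0.0]
        secs[sid + 1] = Section(id=sid + 1, parent_id=sid, type=3,
                                points=np.array([[*p0, d_arm], [*p1, d_arm]]))
        sid += 2
    return Morphology(sections=secs)


@pytest.fixture(scope="session")
def soma_model(passive_params):
    return build_compartmental_model(make_soma_only(), passive_params)


@pytest.fixture(scope="session")
def ball_sticks_model(passive_params):
    return build_compartmental_model(make_ball_and_sticks(),
                                     passive_params, d_lambda=0.05)


@pytest.fixture(scope="session")
def y_model(passive_params):
    return build_compartmental_model(make_y_tree(), passive_params,
                                     d_lambda=0.05)


@pytest.fixture(scope="session")
def human_model():
    """Spine-corrected human-like synthetic cell (coarse discretization —
    the heavy analyses sweep many simulations)."""
    return default_study_model(HUMAN_RECIPE, seed=1, d_lambda=0.1)


@pytest.fixture(scope="session")
def rat_model():
    return default_study_model(RAT_RECIPE, seed=1, d_lambda=0.1)


@pytest.fixture(scope="session")
def moo_cell(passive_params):
    """Small soma+dendrites+axon cell used for spiking-model tests."""
    from humanl23.active import add_axon_stub

    secs = {1: Section(id=1, parent_id=None, type=1,
                       points=np.array([[0.0, 0.0, 0.0, 16.0]]))}
    for k, (dx, dz) in enumerate([(80, 120), (-80, 120)], start=2):
        secs[k] = Section(id=k, parent_id=1, type=3,
                          points=np.array([[0, 0, 0, 1.2], [dx, 0, dz, 0.9]]))
    model = build_compartmental_model(Morphology(sections=secs),
                                      passive_params, d_lambda=0.1)
    return add_axon_stub(model)


@pytest.fixture(scope="session")
def spike_targets(moo_cell):
    """Synthetic spike-train targets from the reference active model."""
    from humanl23.synthetic import generate_spike_train_targets

    targets, stim, ifc, traces, gt = generate_spike_train_targets(
        moo_cell, repeats=10, seed=4)
    return {"targets": targets, "stim": stim, "if_reference": ifc,
            "traces": traces, "ground_truth": gt}


@pytest.fixture(scope="session")
def moo_best_fit(moo_cell, spike_targets):
    """Best model from up to two test-profile evolutionary fits (the
    second optimization runs only if the first misses 2 SD somewhere)."""
    from humanl23.active import DEFAULT_ACTIVE, ParamBounds, moo_fit

    bounds = ParamBounds.around(DEFAULT_ACTIVE, density_factor=2.0)
    best = None
    for s in (0, 1):
        res = moo_fit(moo_cell, spike_targets["targets"], bounds,
                      spike_targets["stim"],
                      if_reference=spike_targets["if_reference"],
                      seed=s, test_profile=True)
        if best is None or res.best.max_distance < best.max_distance:
            best = res.best
        if best.max_distance <= 2.0:
            break
    return best
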