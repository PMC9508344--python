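"""Shared fixtures: synthetic experiments and solved simulations.

The expensive artifacts (generated trial, tracking solutions, predictive
runs) are session-scoped so the whole suite pays for each of them once.
"""
from __future__ import annotations

import numpy as np
import pytest

from sprintopt.model import default_model
from sprintopt.synth import SynthConfig, generate_experiment
from sprintopt.tracking import run_tracking


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def synth_cfg():
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def experiment(synth_cfg, model):
    """Clean synthetic two-step trial (the study conditions)."""
    return generate_experiment(synth_cfg, model)


@pytest.fixture(scope="session")
def tracking_n50(experiment, model):
    """Tracking solution at the reference mesh (used by the recovery checks)."""
    return run_tracking(experiment, model, n_intervals=50, d=3,
                        maxiter=150, tol=2e-4, cutoff=None)


@pytest.fixture(scope="session")
def tracking_n20(experiment, model):
    """Coarser tracking solution seeding the predictive suite."""
    return run_tracking(experiment, model, n_intervals=20, d=3,
                        maxiter=120, tol=2e-4, cutoff=None)


@pytest.fixture(scope="session")
def predictive_suite(tracking_n20, model):
    """All seven free-moment runs plus the two all-tracked references.

    ``none_fixed`` pins the horizon to the tracking value (degenerate
    reproduction check); ``none_free`` leaves it free (objective
    monotonicity reference).
    """
    from sprintopt.predictive import FREE_MOMENT_CONFIGS, run_predictive

    out = {}
    for cfg in FREE_MOMENT_CONFIGS:
        out[cfg] = run_predictive(cfg, tracking_n20, model, mesh_n=20,
                                  tol=3e-4, maxiter=25)
    out["none_fixed"] = run_predictive("none", tracking_n20, model, mesh_n=20,
                                       tol=3e-4, maxiter=25, fix_tf=True)
    out["none_free"] = run_predictive("none", tracking_n20, model, mesh_n=20,
                                      tol=3e-4, maxiter=25)
    return out


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same deterministic stream
    return np.random.default_rng(42)
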