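"""Shared fixtures: plant parameters and session-scoped trained controllers.

Training fixtures run once per session at desk scale (100 units/layer) and
are shared by the behavioral and acceptance tests; everything else is cheap.
"""

import warnings

import numpy as np
import pytest

from armdyn.controller import NetworkParams
from armdyn.plant import ArmParams, MuscleParams
from armdyn.tasks import make_task
from armdyn.training import TrainConfig, evaluate, train


@pytest.fixture(scope="session")
def arm():
    return ArmParams()


@pytest.fixture(scope="session")
def muscles():
    return MuscleParams()


def _train_desk(task_name, recurrent, arm, muscles, seed=0, **cfg_kw):
    task = make_task(task_name)
    params = NetworkParams(n_units=100, recurrent=recurrent)
    defaults = dict(lr=3e-3, relu_leak=0.3, max_epochs=2000, flat_window=300)
    defaults.update(cfg_kw)
    cfg = TrainConfig(**defaults)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result = train(task, params, cfg, muscles, arm, seed=seed)
    batch = evaluate(result.weights, params, task, muscles, arm)
    return {"task": task, "params": params, "result": result, "batch": batch}


@pytest.fixture(scope="session")
def posture_rec(arm, muscles):
    """REC network trained on the posture-perturbation task (desk scale)."""
    return _train_desk("posture", True, arm, muscles)


@pytest.fixture(scope="session")
def posture_norec(arm, muscles):
    """NO-REC network trained on the posture task."""
    return _train_desk("posture", False, arm, muscles)


@pytest.fixture(scope="session")
def reach_rec(arm, muscles):
    """REC network trained on the 32-target delayed reach task."""
    return _train_desk("reach", True, arm, muscles, max_epochs=4000)


@pytest.fixture(scope="session")
def tracking_rec(arm, muscles):
    """REC network trained on the 15-target constant-velocity tracking task."""
    return _train_desk("tracking", True, arm, muscles)
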