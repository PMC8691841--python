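"""BPTT gradients, optimizer behavior, rollout determinism."""

import numpy as np
import pytest

from armdyn.controller import _FIELDS, NetworkParams, Weights, init_weights
from armdyn.plant import ArmParams, MuscleParams
from armdyn.tasks import make_posture_task, make_reach_task, trial_loss
from armdyn.training import (
    Adam,
    TrainConfig,
    loss_and_grads,
    n_network_inputs,
    rollout,
    train,
)


@pytest.fixture(scope="module")
def small_setup():
    arm = ArmParams()
    muscles = MuscleParams()
    task = make_posture_task(arm, hold_steps=5, post_steps=15, penalty_delay_steps=8)
    return arm, muscles, task


def _perturbed_weights(params, n_in, seed=1, scale=0.3):
    rng = np.random.default_rng(seed)
    w = init_weights(params, n_in, rng)
    for f in _FIELDS:
        getattr(w, f)[...] += rng.normal(0, scale, getattr(w, f).shape)
    if not params.recurrent:
        w.w_hh[:] = 0.0
        w.w_oo[:] = 0.0
    return w


@pytest.mark.parametrize(
    "recurrent,feedback",
    [(True, "joint"), (False, "joint"), (True, "cartesian")],
)
def test_bptt_gradient_matches_finite_differences(small_setup, recurrent, feedback):
    """The hand-written reverse pass is exact (leak 0) against central differences."""
    arm, muscles, task = small_setup
    params = NetworkParams(n_units=5, recurrent=recurrent, delay=0.030)
    w = _perturbed_weights(params, n_network_inputs(task, feedback))
    J, grads, _ = loss_and_grads(w, params, task, muscles, arm, feedback=feedback)
    rng = np.random.default_rng(0)
    for f in _FIELDS:
        if f in ("w_hh", "w_oo") and not recurrent:
            continue
        flat = getattr(w, f).reshape(-1)
        for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            eps = 1e-6
            old = flat[i]
            vals = []
            for delta in (eps, -eps):
                flat[i] = old + delta
                b = rollout(w, params, task, muscles, arm, feedback=feedback)
                vals.append(trial_loss(b.x, b.m, b.h, b.o, task))
            flat[i] = old
            g_fd = (vals[0] - vals[1]) / (2 * eps)
            g_an = grads[f].reshape(-1)[i]
            assert g_an == pytest.approx(g_fd, rel=1e-5, abs=1e-10)


def test_gradient_with_delay_routing(small_setup):
    """Gradients stay exact when feedback adjoints must be routed back through the delay."""
    arm, muscles, task = small_setup
    params = NetworkParams(n_units=4, delay=0.050)
    w = _perturbed_weights(params, n_network_inputs(task), seed=3)
    _, grads, _ = loss_and_grads(w, params, task, muscles, arm)
    eps = 1e-6
    flat = w.w_sh.reshape(-1)
    i = 7
    old = flat[i]
    flat[i] = old + eps
    b = rollout(w, params, task, muscles, arm)
    jp = trial_loss(b.x, b.m, b.h, b.o, task)
    flat[i] = old - eps
    b = rollout(w, params, task, muscles, arm)
    jm = trial_loss(b.x, b.m, b.h, b.o, task)
    flat[i] = old
    assert grads["w_sh"].reshape(-1)[i] == pytest.approx((jp - jm) / (2 * eps), rel=1e-5)


def test_adam_matches_ridge_closed_form():
    """Our Adam loop on a quadratic (ridge) objective reaches the closed-form optimum."""
    rng = np.random.default_rng(0)
    n, p = 40, 6
    X = rng.normal(size=(n, p))
    beta_true = rng.normal(size=p)
    y = X @ beta_true + 0.1 * rng.normal(size=n)
    lam = 0.5
    closed = np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ y)

    w = Weights(
        w_sh=np.zeros((1, p)), w_hh=np.zeros((1, 1)), w_ho=np.zeros((1, 1)),
        w_oo=np.zeros((1, 1)), w_ou=np.zeros((6, 1)), b_h=np.zeros(1), b_o=np.zeros(1),
    )
    cfg = TrainConfig(lr=0.05, clip_norm=1e9)
    opt = Adam(w, cfg)
    for _ in range(2000):
        beta = w.w_sh[0]
        grad = 2 * X.T @ (X @ beta - y) + 2 * lam * beta
        grads = {f: np.zeros_like(getattr(w, f)) for f in _FIELDS}
        grads["w_sh"][0] = grad
        opt.step(w, grads)
    assert np.allclose(w.w_sh[0], closed, atol=1e-5)


def test_training_reduces_posture_error(small_setup):
    """Parameter recovery: a briefly trained toy controller beats the untrained one."""
    arm, muscles, _ = small_setup
    task = make_posture_task(arm, hold_steps=10, post_steps=40, penalty_delay_steps=25)
    params = NetworkParams(n_units=24)
    rng = np.random.default_rng(0)
    w0 = init_weights(params, n_network_inputs(task), rng)
    b0 = rollout(w0, params, task, muscles, arm)
    loss0 = trial_loss(b0.x, b0.m, b0.h, b0.o, task)
    cfg = TrainConfig(lr=5e-3, max_epochs=400, flat_window=100, relu_leak=0.3)
    res = train(task, params, cfg, muscles, arm, seed=0)
    assert res.loss_history[-1] < 0.3 * loss0
    # smoothed loss is non-increasing over 100-epoch windows
    h = res.loss_history
    windows = [h[i : i + 100].mean() for i in range(0, len(h) - 100, 100)]
    assert all(b <= a * 1.05 for a, b in zip(windows, windows[1:]))


def test_norec_recurrence_stays_zero(small_setup):
    arm, muscles, task = small_setup
    params = NetworkParams(n_units=8, recurrent=False)
    cfg = TrainConfig(lr=3e-3, max_epochs=50, flat_window=10)
    res = train(task, params, cfg, muscles, arm, seed=0)
    assert np.all(res.weights.w_hh == 0)
    assert np.all(res.weights.w_oo == 0)


def test_rollout_bit_identical(small_setup):
    arm, muscles, task = small_setup
    params = NetworkParams(n_units=6)
    w = _perturbed_weights(params, n_network_inputs(task), seed=5)
    b1 = rollout(w, params, task, muscles, arm)
    b2 = rollout(w, params, task, muscles, arm)
    assert np.array_equal(b1.x, b2.x) and np.array_equal(b1.o, b2.o)


def test_feedback_is_delayed_plant_state(small_setup):
    arm, muscles, task = small_setup
    params = NetworkParams(n_units=6, delay=0.050)
    w = _perturbed_weights(params, n_network_inputs(task), seed=6)
    b = rollout(w, params, task, muscles, arm)
    d = params.delay_steps
    assert np.allclose(b.fb_x[:, d:], b.x[:, :-d])
    assert np.allclose(b.fb_x[:, :d], b.x[:, :1])  # prefill with the initial state
    assert np.allclose(b.fb_m[:, d:], b.m[:, :-d])


def test_feedback_mode_none_clamps_inputs(small_setup):
    arm, muscles, task = small_setup
    params = NetworkParams(n_units=6)
    w = _perturbed_weights(params, n_network_inputs(task), seed=7)
    b = rollout(w, params, task, muscles, arm, feedback_mode="none")
    assert np.allclose(b.fb_x, b.fb_x[:, :1])
    assert np.allclose(b.fb_m, 0.0)


def test_motor_noise_requires_rng_and_perturbs(small_setup):
    arm, muscles, task = small_setup
    params = NetworkParams(n_units=6)
    w = _perturbed_weights(params, n_network_inputs(task), seed=8)
    with pytest.raises(ValueError):
        rollout(w, params, task, muscles, arm, noise_level=0.8)
    b0 = rollout(w, params, task, muscles, arm)
    b1 = rollout(w, params, task, muscles, arm, noise_level=0.8,
                 rng=np.random.default_rng(0))
    assert not np.allclose(b0.m, b1.m)
    assert np.all(b1.m >= 0)
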