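"""Training the controller by backpropagation-through-time (BPTT).

The rollout of controller + arm is a fixed, explicitly differentiable
computation graph, so the gradient of the trial loss with respect to every
weight matrix is computed by a hand-written reverse pass: the network
equations are linearized analytically and the arm dynamics contribute their
analytic step Jacobians (``plant.step_arm_jacobians``).  Sensory feedback
delays route adjoints backwards in time by the corresponding number of steps.
Optimization uses Adam with global-norm gradient clipping.

The forward rollout supports the evaluation-time variants used by the
robustness analyses: cartesian hand feedback instead of joint feedback,
gated ("pulse") or absent feedback, and multiplicative signal-dependent
motor noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from armdyn.controller import NetworkParams, Weights, _FIELDS, init_weights
from armdyn.plant import (
    ArmParams,
    MuscleParams,
    hand_jacobian,
    hand_position,
    hand_velocity,
    step_arm,
    step_arm_jacobians,
)
from armdyn.tasks import TaskBatch, trial_loss


@dataclass
class TrainConfig:
    """Optimizer settings and convergence rule.

    Training stops when the loss drops below ``loss_tol`` and its running
    mean changes by less than ``flat_tol`` over ``flat_window`` epochs, or at
    ``max_epochs`` (returning the best weights with a warning flag).
    """

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    clip_norm: float = 1.0
    relu_leak: float = 0.1
    lr_decay: str = "cosine"  # "cosine" anneals to lr_min_frac * lr; "none" keeps lr fixed
    lr_min_frac: float = 0.05
    max_epochs: int = 10_000
    loss_tol: float = 5e-4
    flat_tol: float = 1e-6
    flat_window: int = 500
    verbose: bool = False


@dataclass
class TrialBatch:
    """Rollout record: per-condition time series of everything the analyses need."""

    x: np.ndarray  # (C, T, 4) joint state
    m: np.ndarray  # (C, T, 6) muscle activations
    h: np.ndarray  # (C, T, N) input-layer activity
    o: np.ndarray  # (C, T, N) output-layer activity
    inputs: np.ndarray  # (C, T, K) full network input I_t
    fb_x: np.ndarray  # (C, T, 4 or 4) delayed kinematic feedback as seen by the network
    fb_m: np.ndarray  # (C, T, 6) delayed muscle feedback
    task: TaskBatch | None = None

    def hand_paths(self, arm: ArmParams) -> np.ndarray:
        return hand_position(self.x, arm)


def _feedback_dim(feedback: str) -> int:
    if feedback not in ("joint", "cartesian"):
        raise ValueError("feedback must be 'joint' or 'cartesian'")
    return 4


def n_network_inputs(task: TaskBatch, feedback: str = "joint") -> int:
    """Total input dimensionality: task-goal channels + kinematic + muscle feedback."""
    return task.n_task_inputs + _feedback_dim(feedback) + 6


def _kin_signal(x: np.ndarray, feedback: str, arm: ArmParams) -> np.ndarray:
    if feedback == "joint":
        return x
    pos = hand_position(x, arm)
    vel = hand_velocity(x, arm)
    return np.concatenate([pos, vel], axis=-1)


def rollout(
    weights: Weights,
    params: NetworkParams,
    task: TaskBatch,
    muscles: MuscleParams | None = None,
    arm: ArmParams | None = None,
    feedback: str = "joint",
    feedback_mode: str = "continuous",
    pulse_steps: int = 20,
    noise_level: float = 0.0,
    rng: np.random.Generator | None = None,
) -> TrialBatch:
    """Deterministic forward simulation of all task conditions.

    feedback_mode:
      * ``continuous`` — normal delayed feedback at every step;
      * ``pulse`` — feedback frozen at its pre/early-perturbation value
        outside the first ``pulse_steps`` (200 ms) after the perturbation;
      * ``none`` — feedback clamped to the initial state throughout.
    ``noise_level`` adds multiplicative Gaussian noise to the rectified motor
    command (variance = level x command^2); used at evaluation time only.
    """
    muscles = muscles or MuscleParams()
    arm = arm or ArmParams()
    C, T = task.n_conditions, task.n_steps
    N = params.n_units
    d = params.delay_steps
    if noise_level > 0 and rng is None:
        raise ValueError("motor noise requires an rng")

    x = np.empty((C, T, 4))
    m = np.zeros((C, T, 6))
    h = np.zeros((C, T, N))
    o = np.zeros((C, T, N))
    K = n_network_inputs(task, feedback)
    inputs = np.empty((C, T, K))
    fb_x_all = np.empty((C, T, 4))
    fb_m_all = np.empty((C, T, 6))
    x[:, 0] = task.x0

    kin0 = _kin_signal(np.broadcast_to(task.x0, (C, 4)), feedback, arm)
    gate = _feedback_gate(task, feedback_mode, pulse_steps, d, T)

    for t in range(T):
        j = t - d
        if j >= 0 and gate[t]:
            fb_x = _kin_signal(x[:, j], feedback, arm)
            fb_m = m[:, j]
        else:
            # before the delay has elapsed, or gated out: pre-perturbation values
            fb_x = kin0
            fb_m = np.zeros((C, 6))
        fb_x_all[:, t] = fb_x
        fb_m_all[:, t] = fb_m
        inputs[:, t] = np.concatenate([task.task_input[:, t], fb_x, fb_m], axis=1)

        if t == T - 1:
            break
        if params.recurrent:
            h[:, t + 1] = (1 - params.l_n) * h[:, t] + params.l_n * np.tanh(
                inputs[:, t] @ weights.w_sh.T + h[:, t] @ weights.w_hh.T + weights.b_h
            )
            o[:, t + 1] = (1 - params.l_n) * o[:, t] + params.l_n * np.tanh(
                h[:, t] @ weights.w_ho.T + o[:, t] @ weights.w_oo.T + weights.b_o
            )
        else:
            h[:, t + 1] = np.tanh(inputs[:, t] @ weights.w_sh.T + weights.b_h)
            o[:, t + 1] = np.tanh(h[:, t] @ weights.w_ho.T + weights.b_o)
        drive = np.maximum(o[:, t] @ weights.w_ou.T, 0.0)
        if noise_level > 0:
            drive = np.maximum(
                drive * (1.0 + np.sqrt(noise_level) * rng.standard_normal(drive.shape)), 0.0
            )
        m[:, t + 1] = (1 - params.l_m) * m[:, t] + params.l_m * drive
        x[:, t + 1] = step_arm(x[:, t], m[:, t], muscles, arm, task.loads[:, t])

    return TrialBatch(x=x, m=m, h=h, o=o, inputs=inputs, fb_x=fb_x_all, fb_m=fb_m_all, task=task)


def _feedback_gate(
    task: TaskBatch, feedback_mode: str, pulse_steps: int, delay_steps: int, T: int
) -> np.ndarray:
    """Per-step flag: does I_t carry live (gradient-bearing) feedback from x_{t-delay}?"""
    gate = np.ones(T, dtype=bool)
    if feedback_mode == "none":
        gate[:] = False
    elif feedback_mode == "pulse":
        onset = task.load_onset or 0
        for t in range(T):
            j = t - delay_steps
            gate[t] = onset <= j <= onset + pulse_steps
    elif feedback_mode != "continuous":
        raise ValueError(f"unknown feedback_mode {feedback_mode!r}")
    return gate


def loss_and_grads(
    weights: Weights,
    params: NetworkParams,
    task: TaskBatch,
    muscles: MuscleParams,
    arm: ArmParams,
    feedback: str = "joint",
    feedback_mode: str = "continuous",
    pulse_steps: int = 20,
    relu_leak: float = 0.0,
) -> tuple[float, dict[str, np.ndarray], TrialBatch]:
    """Trial loss and its gradient w.r.t. every weight array (reverse-mode BPTT).

    With ``relu_leak = 0`` the gradient is exact.  A positive leak substitutes
    a leaky-rectifier slope for the muscle nonlinearity's zero branch in the
    backward pass only — the usual surrogate-gradient remedy for rectifier
    death, which otherwise silences the muscle pathway early in training when
    the hold-period penalties push all drives negative.
    """
    batch = rollout(
        weights, params, task, muscles, arm, feedback=feedback,
        feedback_mode=feedback_mode, pulse_steps=pulse_steps,
    )
    x, m, h, o, inputs = batch.x, batch.m, batch.h, batch.o, batch.inputs
    C, T = task.n_conditions, task.n_steps
    N = params.n_units
    d = params.delay_steps
    ln, lm = params.l_n, params.l_m
    w = task.weights
    J = trial_loss(x, m, h, o, task)
    norm = 1.0 / (C * T)

    # adjoints of the state variables at every step
    gx = task.kin_mask[None, :, None] * (x - task.x_star) * norm
    gm = task.alpha_t[None, :, None] * m * norm
    gh = w.beta * h * norm
    go = w.gamma * o * norm

    # cached nonlinearity slopes (recompute pre-activations from stored states)
    if params.recurrent:
        th_h = (h[:, 1:] - (1 - ln) * h[:, :-1]) / ln
        th_o = (o[:, 1:] - (1 - ln) * o[:, :-1]) / ln
    else:
        th_h = h[:, 1:]
        th_o = o[:, 1:]
    d_h = 1.0 - th_h**2
    d_o = 1.0 - th_o**2
    drive_mask = np.where((o @ weights.w_ou.T) > 0.0, 1.0, relu_leak)  # (C, T, 6)

    # plant Jacobians for every transition, one vectorized call
    Jx, Jm = step_arm_jacobians(
        x[:, :-1].reshape(-1, 4), m[:, :-1].reshape(-1, 6), muscles, arm,
        task.loads[:, :-1].reshape(-1, 2),
    )
    Jx = Jx.reshape(C, T - 1, 4, 4)
    Jm = Jm.reshape(C, T - 1, 4, 6)

    gate = _feedback_gate(task, feedback_mode, pulse_steps, d, T)
    n_task = task.n_task_inputs
    kin_sl = slice(n_task, n_task + 4)
    mus_sl = slice(n_task + 4, n_task + 10)
    if feedback == "cartesian":
        Jkin = hand_jacobian(x, arm)  # (C, T, 4, 4)

    rec = params.recurrent
    N6 = weights.w_ou.shape[0]
    zh_all = np.zeros((C, T - 1, N))
    zo_all = np.zeros((C, T - 1, N))
    zm_all = np.zeros((C, T - 1, N6))
    for t in range(T - 2, -1, -1):
        a_h = gh[:, t + 1]
        a_o = go[:, t + 1]
        a_m = gm[:, t + 1]
        a_x = gx[:, t + 1]
        if rec:
            gh[:, t] += (1 - ln) * a_h
            go[:, t] += (1 - ln) * a_o
            z_h = ln * d_h[:, t] * a_h
            z_o = ln * d_o[:, t] * a_o
        else:
            z_h = d_h[:, t] * a_h
            z_o = d_o[:, t] * a_o
        zh_all[:, t] = z_h
        zo_all[:, t] = z_o
        gh[:, t] += z_o @ weights.w_ho
        if rec:
            gh[:, t] += z_h @ weights.w_hh
            go[:, t] += z_o @ weights.w_oo
        z_m = lm * (a_m * drive_mask[:, t])
        zm_all[:, t] = z_m
        go[:, t] += z_m @ weights.w_ou
        gm[:, t] += (1 - lm) * a_m
        gx[:, t] += np.einsum("cij,ci->cj", Jx[:, t], a_x)
        gm[:, t] += np.einsum("cij,ci->cj", Jm[:, t], a_x)
        # route input adjoints back through the delay lines
        j = t - d
        if j >= 0 and gate[t]:
            gI = z_h @ weights.w_sh  # (C, K)
            g_kin = gI[:, kin_sl]
            if feedback == "cartesian":
                gx[:, j] += np.einsum("cij,ci->cj", Jkin[:, j], g_kin)
            else:
                gx[:, j] += g_kin
            gm[:, j] += gI[:, mus_sl]

    # weight gradients: one batched product per matrix over all (condition, step) pairs
    zh_flat = zh_all.reshape(-1, N).T
    zo_flat = zo_all.reshape(-1, N).T
    zm_flat = zm_all.reshape(-1, N6).T
    h_flat = h[:, :-1].reshape(-1, N)
    o_flat = o[:, :-1].reshape(-1, N)
    grads = {
        "w_sh": zh_flat @ inputs[:, :-1].reshape(-1, inputs.shape[2]),
        "b_h": zh_flat.sum(axis=1),
        "w_ho": zo_flat @ h_flat,
        "b_o": zo_flat.sum(axis=1),
        "w_ou": zm_flat @ o_flat,
    }
    if rec:
        grads["w_hh"] = zh_flat @ h_flat
        grads["w_oo"] = zo_flat @ o_flat
    else:
        grads["w_hh"] = np.zeros_like(weights.w_hh)
        grads["w_oo"] = np.zeros_like(weights.w_oo)
    return J, grads, batch


class Adam:
    """Plain Adam on a list of named arrays, with global-norm gradient clipping."""

    def __init__(self, weights: Weights, config: TrainConfig):
        self.cfg = config
        self.t = 0
        self.m = {f: np.zeros_like(getattr(weights, f)) for f in _FIELDS}
        self.v = {f: np.zeros_like(getattr(weights, f)) for f in _FIELDS}

    def step(self, weights: Weights, grads: dict[str, np.ndarray], lr: float | None = None) -> None:
        c = self.cfg
        lr = c.lr if lr is None else lr
        gnorm = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
        scale = min(1.0, c.clip_norm / (gnorm + 1e-12))
        self.t += 1
        b1t = 1 - c.beta1**self.t
        b2t = 1 - c.beta2**self.t
        for f in _FIELDS:
            g = grads[f] * scale
            self.m[f] = c.beta1 * self.m[f] + (1 - c.beta1) * g
            self.v[f] = c.beta2 * self.v[f] + (1 - c.beta2) * g**2
            update = lr * (self.m[f] / b1t) / (np.sqrt(self.v[f] / b2t) + c.eps)
            getattr(weights, f)[...] -= update


@dataclass
class TrainResult:
    weights: Weights
    loss_history: np.ndarray
    converged: bool
    epochs: int


def train(
    task: TaskBatch,
    params: NetworkParams,
    config: TrainConfig | None = None,
    muscles: MuscleParams | None = None,
    arm: ArmParams | None = None,
    seed: int = 0,
    feedback: str = "joint",
    feedback_mode: str = "continuous",
    init_weights_override: Weights | None = None,
) -> TrainResult:
    """Full-batch Adam/BPTT optimization over all task conditions.

    Seed-reproducible; NO-REC networks keep their recurrent matrices pinned at
    zero throughout.  Returns the best-loss weights seen.
    """
    config = config or TrainConfig()
    muscles = muscles or MuscleParams()
    arm = arm or ArmParams()
    rng = np.random.default_rng(seed)
    if init_weights_override is not None:
        weights = init_weights_override.copy()
    else:
        weights = init_weights(params, n_network_inputs(task, feedback), rng)
    opt = Adam(weights, config)
    history = []
    best = (np.inf, weights.copy())
    converged = False
    for epoch in range(config.max_epochs):
        J, grads, _ = loss_and_grads(
            weights, params, task, muscles, arm, feedback=feedback,
            feedback_mode=feedback_mode, relu_leak=config.relu_leak,
        )
        if not np.isfinite(J):
            raise FloatingPointError(f"training diverged at epoch {epoch} (loss={J})")
        history.append(J)
        if J < best[0]:
            best = (J, weights.copy())
        if config.lr_decay == "cosine":
            frac = epoch / max(config.max_epochs - 1, 1)
            lr = config.lr * (
                config.lr_min_frac
                + (1 - config.lr_min_frac) * 0.5 * (1 + np.cos(np.pi * frac))
            )
        else:
            lr = config.lr
        opt.step(weights, grads, lr=lr)
        if not params.recurrent:
            weights.w_hh[:] = 0.0
            weights.w_oo[:] = 0.0
        if config.verbose and epoch % 100 == 0:
            print(f"epoch {epoch:5d}  loss {J:.6g}")
        wlen = config.flat_window
        if epoch >= 2 * wlen and J < config.loss_tol:
            recent = np.mean(history[-wlen:])
            prev = np.mean(history[-2 * wlen : -wlen])
            if abs(prev - recent) < config.flat_tol:
                converged = True
                break
    if not converged:
        warnings.warn(
            "training stopped at max_epochs without meeting the convergence rule; "
            "returning the best checkpoint",
            RuntimeWarning,
        )
    return TrainResult(
        weights=best[1],
        loss_history=np.asarray(history),
        converged=converged,
        epochs=len(history),
    )


def evaluate(
    weights: Weights,
    params: NetworkParams,
    task: TaskBatch,
    muscles: MuscleParams | None = None,
    arm: ArmParams | None = None,
    **rollout_kwargs,
) -> TrialBatch:
    """Deterministic rollout of trained weights over all conditions."""
    return rollout(weights, params, task, muscles, arm, **rollout_kwargs)
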