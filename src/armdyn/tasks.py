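"""Task definitions: posture perturbation, delayed center-out reach, target tracking.

Each task is expressed as a :class:`TaskBatch` — dense per-condition arrays of
external load torques, desired joint-state trajectories, task-goal input
channels, and penalty schedules — which the trainer and evaluator consume
directly.

Tasks
-----
posture
    Hold the hand at the start posture while one of eight constant joint
    torques (0.2 N m: EF, EE, SF, SE and the four two-joint combinations) is
    applied after a 500 ms hold.  A ninth, load-free condition is included for
    training; analyses use the eight loaded conditions.  The network receives
    no information about the load other than delayed limb feedback.
reach
    Hold 500 ms at the start; a GO cue then releases a reach to 1 of 32 radial
    targets (16 directions x {2 cm, 5 cm}), to be acquired within 500 ms and
    held for the rest of the trial.
tracking
    After a 300 ms rest, the target moves radially outward at constant
    velocity, reaching 5 cm at trial end (15 directions); the ramping target
    is fed to the network as input and position and velocity errors are
    penalized at every step.

The per-trial loss is the summed squared kinematic error (inside each task's
penalty windows) plus quadratic penalties on muscle, input-layer and
output-layer activity, normalized by 1 / (2 C T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from armdyn.plant import ArmParams, hand_position, inverse_kinematics

START_ANGLES = np.array([np.pi / 4, np.pi / 2])  # (shoulder, elbow), rad

POSTURE_LOADS = 0.2 * np.array(
    [
        [+1, 0],   # SF
        [-1, 0],   # SE
        [0, +1],   # EF
        [0, -1],   # EE
        [+1, +1],  # SF+EF
        [+1, -1],  # SF+EE
        [-1, +1],  # SE+EF
        [-1, -1],  # SE+EE
    ]
)  # (shoulder, elbow) N m


@dataclass
class LossWeights:
    """Penalty weights of the training loss.

    ``alpha`` scales the muscle-activity penalty, ``beta``/``gamma`` the
    input- and output-layer activity penalties; ``alpha_hold`` is the larger
    muscle penalty applied during the posture task's pre-load period so the
    muscles do not co-contract in anticipation of the load.
    """

    alpha: float = 1e-4
    beta: float = 1e-5
    gamma: float = 1e-5
    alpha_hold: float = 1e-2


def default_loss_weights(task: str) -> LossWeights:
    # alpha/beta/gamma each take one of two published values; the assignment per
    # task keeps the stronger activity penalty wherever the weaker one lets the
    # controller adopt fast resonant strategies the modeled system should not show
    if task == "posture":
        return LossWeights(alpha=1e-4, beta=1e-5, gamma=1e-5)
    if task == "reach":
        return LossWeights(alpha=1e-3, beta=1e-6, gamma=1e-6)
    if task == "tracking":
        return LossWeights(alpha=1e-3, beta=1e-5, gamma=1e-5)
    raise ValueError(f"unknown task {task!r}")


@dataclass
class TaskBatch:
    """Dense description of all conditions of one task.

    Arrays: ``loads`` (C, T, 2) external joint torques; ``x_star`` (C, T, 4)
    desired joint state in the package state layout; ``task_input`` (C, T, K)
    goal channels fed to the network (K = 0 for posture); ``kin_mask`` (T,)
    kinematic-penalty window indicator; ``alpha_t`` (T,) per-step muscle
    penalty.
    """

    task: str
    n_conditions: int
    n_steps: int
    dt: float
    loads: np.ndarray
    x_star: np.ndarray
    task_input: np.ndarray
    kin_mask: np.ndarray
    alpha_t: np.ndarray
    weights: LossWeights
    x0: np.ndarray
    load_onset: int | None = None
    go_step: int | None = None
    motion_onset: int | None = None
    analysis_conditions: np.ndarray | None = None

    @property
    def n_task_inputs(self) -> int:
        return self.task_input.shape[2]


def _start_state() -> np.ndarray:
    ths, the = START_ANGLES
    return np.array([the, ths, 0.0, 0.0])


def make_posture_task(
    arm: ArmParams | None = None,
    hold_steps: int = 50,
    post_steps: int = 150,
    include_null: bool = True,
    penalty_delay_steps: int = 100,
    weights: LossWeights | None = None,
) -> TaskBatch:
    """Posture-perturbation task: 500 ms hold, then a constant load to trial end.

    The kinematic penalty runs during the initial hold and from 1000 ms after
    load onset to the trial end (accurate return plus stable hold); muscle
    activity before the load is penalized at ``alpha_hold``.
    """
    arm = arm or ArmParams()
    weights = weights or default_loss_weights("posture")
    T = hold_steps + post_steps
    loads_list = list(POSTURE_LOADS)
    if include_null:
        loads_list.append(np.zeros(2))
    C = len(loads_list)
    loads = np.zeros((C, T, 2))
    for c, lv in enumerate(loads_list):
        loads[c, hold_steps:, :] = lv
    x0 = _start_state()
    x_star = np.broadcast_to(x0, (C, T, 4)).copy()
    kin_mask = np.zeros(T)
    kin_mask[:hold_steps] = 1.0
    kin_mask[hold_steps + penalty_delay_steps:] = 1.0
    alpha_t = np.full(T, weights.alpha)
    alpha_t[:hold_steps] = weights.alpha_hold
    return TaskBatch(
        task="posture",
        n_conditions=C,
        n_steps=T,
        dt=arm.dt,
        loads=loads,
        x_star=x_star,
        task_input=np.zeros((C, T, 0)),
        kin_mask=kin_mask,
        alpha_t=alpha_t,
        weights=weights,
        x0=x0,
        load_onset=hold_steps,
        analysis_conditions=np.arange(len(POSTURE_LOADS)),
    )


def reach_targets(arm: ArmParams, n_directions: int = 16, radii=(0.02, 0.05)) -> np.ndarray:
    """Radial target hand positions (C, 2) around the start-posture hand location."""
    center = hand_position(_start_state(), arm)
    angles = 2 * np.pi * np.arange(n_directions) / n_directions
    targets = [
        center + r * np.array([np.cos(a), np.sin(a)]) for r in radii for a in angles
    ]
    return np.array(targets)


def make_reach_task(
    arm: ArmParams | None = None,
    delay_steps: int = 50,
    move_steps: int = 100,
    n_directions: int = 16,
    radii=(0.02, 0.05),
    weights: LossWeights | None = None,
    go_cue_sd: float = 0.020,
) -> TaskBatch:
    """Delayed center-out reach: hold with the target shown, GO cue, reach and hold.

    Task inputs are the target joint angles (step signal, on from trial start)
    plus the smoothed GO-cue channel (high = hold, low = move).  The kinematic
    penalty covers the initial hold and everything from 500 ms after GO.
    """
    from armdyn.controller import smoothed_go_cue

    arm = arm or ArmParams()
    weights = weights or default_loss_weights("reach")
    T = delay_steps + move_steps
    targets = reach_targets(arm, n_directions, radii)
    C = len(targets)
    x0 = _start_state()
    th_target = inverse_kinematics(targets, arm)  # (C, 2) (sho, elb)
    x_target = np.zeros((C, 4))
    x_target[:, 0] = th_target[:, 1]
    x_target[:, 1] = th_target[:, 0]

    acquire = delay_steps + 50  # 500 ms after GO
    x_star = np.empty((C, T, 4))
    x_star[:, :acquire, :] = x0
    x_star[:, acquire:, :] = x_target[:, None, :]
    kin_mask = np.zeros(T)
    kin_mask[:delay_steps] = 1.0
    kin_mask[acquire:] = 1.0

    cue = smoothed_go_cue(T, delay_steps, arm.dt, go_cue_sd)
    task_input = np.empty((C, T, 3))
    task_input[:, :, 0] = th_target[:, None, 0]
    task_input[:, :, 1] = th_target[:, None, 1]
    task_input[:, :, 2] = cue[None, :]

    return TaskBatch(
        task="reach",
        n_conditions=C,
        n_steps=T,
        dt=arm.dt,
        loads=np.zeros((C, T, 2)),
        x_star=x_star,
        task_input=task_input,
        kin_mask=kin_mask,
        alpha_t=np.full(T, weights.alpha),
        weights=weights,
        x0=x0,
        go_step=delay_steps,
    )


def make_tracking_task(
    arm: ArmParams | None = None,
    rest_steps: int = 30,
    motion_steps: int = 120,
    n_directions: int = 15,
    radius: float = 0.05,
    weights: LossWeights | None = None,
) -> TaskBatch:
    """Constant-velocity tracking: the target ramps radially outward to 5 cm.

    The ramping target position (as joint angles) is the task input; position
    and velocity errors are penalized at every step, so the desired joint
    trajectory carries nonzero velocities during the ramp.
    """
    arm = arm or ArmParams()
    weights = weights or default_loss_weights("tracking")
    T = rest_steps + motion_steps
    x0 = _start_state()
    center = hand_position(x0, arm)
    angles = 2 * np.pi * np.arange(n_directions) / n_directions
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    C = n_directions

    frac = np.zeros(T)
    ramp = np.arange(1, motion_steps + 1) / motion_steps
    frac[rest_steps:] = ramp
    hand_targets = center[None, None, :] + radius * frac[None, :, None] * dirs[:, None, :]
    th_target = inverse_kinematics(hand_targets, arm)  # (C, T, 2)

    x_star = np.zeros((C, T, 4))
    x_star[:, :, 0] = th_target[:, :, 1]
    x_star[:, :, 1] = th_target[:, :, 0]
    # desired joint velocities: finite differences of the target angles
    vel = np.gradient(th_target, arm.dt, axis=1)
    x_star[:, :, 2] = vel[:, :, 1]
    x_star[:, :, 3] = vel[:, :, 0]

    task_input = th_target.copy()  # channels (sho, elb)

    return TaskBatch(
        task="tracking",
        n_conditions=C,
        n_steps=T,
        dt=arm.dt,
        loads=np.zeros((C, T, 2)),
        x_star=x_star,
        task_input=task_input,
        kin_mask=np.ones(T),
        alpha_t=np.full(T, weights.alpha),
        weights=weights,
        x0=x0,
        motion_onset=rest_steps,
    )


def make_task(task: str, **kwargs) -> TaskBatch:
    """Dispatch to the posture / reach / tracking builders."""
    builders = {
        "posture": make_posture_task,
        "reach": make_reach_task,
        "tracking": make_tracking_task,
    }
    if task not in builders:
        raise ValueError(f"unknown task {task!r}")
    return builders[task](**kwargs)


def load_task_config(path) -> TaskBatch:
    """Build a task from a YAML file: a ``task`` name plus builder keyword arguments.

    Example::

        task: posture
        hold_steps: 50
        post_steps: 150
        include_null: true
        weights: {alpha: 1.0e-4, beta: 1.0e-5, gamma: 1.0e-5}
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    name = cfg.pop("task")
    if "weights" in cfg:
        cfg["weights"] = LossWeights(**cfg["weights"])
    return make_task(name, **cfg)


def trial_loss(
    x: np.ndarray,
    m: np.ndarray,
    h: np.ndarray,
    o: np.ndarray,
    batch: TaskBatch,
) -> float:
    """Total training cost J = 1/(2 C T) sum over conditions and steps.

    Per step: masked squared kinematic error ||x - x*||^2 plus
    alpha_t ||m||^2 + beta ||h||^2 + gamma ||o||^2.
    """
    C, T = batch.n_conditions, batch.n_steps
    if x.shape[:2] != (C, T):
        raise ValueError("trajectory does not cover all conditions and steps")
    w = batch.weights
    kin = np.sum(batch.kin_mask[None, :] * np.sum((x - batch.x_star) ** 2, axis=2))
    musc = np.sum(batch.alpha_t[None, :] * np.sum(m**2, axis=2))
    act = w.beta * np.sum(h**2) + w.gamma * np.sum(o**2)
    return float((kin + musc + act) / (2.0 * C * T))
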