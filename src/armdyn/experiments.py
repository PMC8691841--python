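"""End-to-end experiments: train a controller, roll out, analyze population dynamics.

This module wires the pieces together the way the headline analyses use
them: build unit x condition x time tensors for the four signal classes
(output layer, input layer, muscles, kinematics) from an evaluated rollout,
apply the task-specific analysis windows, run the constrained/unconstrained
dynamical fits with TME surrogate nulls (network layers) or down-sampling
controls (muscle/kinematic signals), decode the rotation planes from the
sensory feedback, and run the robustness analyses (current ratios, motor
noise, feedback-delay sweep, cartesian-feedback variant).

Analysis windows
----------------
posture   70-370 ms after load onset (shifted past the 50 ms feedback delay)
reach     first 300 ms after movement onset (5%-of-peak hand-speed criterion)
tracking  movement onset to trial end
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from armdyn.controller import NetworkParams, Weights
from armdyn.jpca import (
    JPCAResult,
    PopulationTensor,
    downsample_compare,
    empirical_p_below,
    jpca,
)
from armdyn.plant import ArmParams, MuscleParams, hand_position, hand_velocity
from armdyn.tasks import TaskBatch, make_task
from armdyn.tme import TMENull, tme_test
from armdyn.training import TrainConfig, TrialBatch, evaluate, train


@dataclass
class ScaleConfig:
    """Problem sizes and optimizer budget for one experiment run.

    The defaults are the desk scale used throughout the analyses here:
    100 units per layer trained with a correspondingly larger Adam step.
    The full-scale model (500 units, lr 1e-3) is reachable through the same
    fields.
    """

    n_units: int = 100
    lr: float = 3e-3
    max_epochs: int = 3000
    n_surrogates: int = 200
    n_downsample: int = 200
    flat_window: int = 300

    def network_params(self, **overrides) -> NetworkParams:
        kw = dict(n_units=self.n_units)
        kw.update(overrides)
        return NetworkParams(**kw)

    def train_config(self) -> TrainConfig:
        return TrainConfig(lr=self.lr, max_epochs=self.max_epochs, flat_window=self.flat_window)


DESK_SCALE = ScaleConfig()


def movement_onset(batch: TrialBatch, arm: ArmParams, threshold: float = 0.05) -> np.ndarray:
    """Per-condition movement onset: first step where hand speed exceeds
    ``threshold`` x that condition's peak speed."""
    speed = np.linalg.norm(hand_velocity(batch.x, arm), axis=2)  # (C, T)
    peaks = speed.max(axis=1)
    onsets = np.empty(len(speed), dtype=int)
    for c, (sp, pk) in enumerate(zip(speed, peaks)):
        above = np.nonzero(sp > threshold * pk)[0]
        onsets[c] = above[0] if above.size else 0
    return onsets


def analysis_window_steps(
    task: TaskBatch,
    batch: TrialBatch,
    arm: ArmParams,
    delay_steps: int = 5,
    window_steps: int = 31,
) -> np.ndarray:
    """Step indices (C, L) of the analysis window for each condition.

    Posture: a fixed window starting ``delay + 20 ms`` after load onset
    (70-370 ms at the standard 50 ms delay; 0-300 ms at zero delay).  Reach:
    the first 300 ms after per-condition movement onset.  Tracking: movement
    onset (shared across conditions) to trial end.
    """
    T = task.n_steps
    C = task.n_conditions
    if task.task == "posture":
        start = task.load_onset + (delay_steps + 2 if delay_steps > 0 else 0)
        stop = min(start + window_steps, T)
        idx = np.arange(start, stop)
        return np.broadcast_to(idx, (C, len(idx))).copy()
    if task.task == "reach":
        onsets = movement_onset(batch, arm)
        onsets = np.minimum(onsets, T - window_steps)
        return onsets[:, None] + np.arange(window_steps)[None, :]
    if task.task == "tracking":
        onsets = movement_onset(batch, arm)
        start = int(np.median(onsets))
        idx = np.arange(start, T)
        return np.broadcast_to(idx, (C, len(idx))).copy()
    raise ValueError(f"unknown task {task.task!r}")


def population_tensors(
    batch: TrialBatch,
    task: TaskBatch,
    arm: ArmParams,
    steps: np.ndarray,
    cartesian_kinematics: bool = False,
) -> dict[str, PopulationTensor]:
    """Windowed tensors for the four signal classes, restricted to analysis conditions."""
    conds = (
        task.analysis_conditions
        if task.analysis_conditions is not None
        else np.arange(task.n_conditions)
    )
    L = steps.shape[1]
    dt = task.dt

    def gather(sig: np.ndarray) -> np.ndarray:
        # sig (C, T, D) -> (D, C_sel, L) using per-condition windows
        picked = np.stack([sig[c, steps[c]] for c in conds], axis=0)  # (C_sel, L, D)
        return np.moveaxis(picked, 2, 0)

    if cartesian_kinematics:
        kin = np.concatenate(
            [hand_position(batch.x, arm), hand_velocity(batch.x, arm)], axis=2
        )
    else:
        kin = batch.x
    times = dt * np.arange(L)
    return {
        "output": PopulationTensor(gather(batch.o), dt, "network", times),
        "input": PopulationTensor(gather(batch.h), dt, "network", times),
        "muscle": PopulationTensor(gather(batch.m), dt, "muscle", times),
        "kinematics": PopulationTensor(gather(kin), dt, "kinematics", times),
    }


@dataclass
class ExperimentReport:
    """Everything one task experiment produced, traceable to its seed/config."""

    task: str
    recurrent: bool
    seed: int
    config: dict
    jpca_results: dict[str, JPCAResult]
    tme_nulls: dict[str, TMENull]
    downsample: dict[str, dict]
    downsample_p: dict[str, dict]
    decode_r2: dict[str, float | list]
    training_converged: bool = True

    def summary(self) -> dict:
        """JSON-serializable digest (reproducible byte-for-byte for a fixed seed/config)."""
        out = {
            "task": self.task,
            "recurrent": self.recurrent,
            "seed": self.seed,
            "config": self.config,
            "signals": {},
            "decode_r2": self.decode_r2,
        }
        for name, res in self.jpca_results.items():
            entry = {
                "r2_constrained": round(res.r2_constrained, 6),
                "r2_unconstrained": round(res.r2_unconstrained, 6),
                "plane_frequencies_hz": [round(f, 4) for f in res.plane_frequencies],
                "plane_vaf": [round(v, 6) for v in res.plane_vaf],
            }
            if name in self.tme_nulls:
                null = self.tme_nulls[name]
                entry["tme"] = {
                    "p_constrained": null.p_constrained,
                    "p_unconstrained": null.p_unconstrained,
                    "median_surrogate_constrained": float(
                        np.median(null.surrogate_constrained)
                    ),
                }
            if name in self.downsample_p:
                entry["downsample_p"] = self.downsample_p[name]
            out["signals"][name] = entry
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


def decode_planes_from_feedback(
    result: JPCAResult,
    batch: TrialBatch,
    task: TaskBatch,
    steps: np.ndarray,
    include_task_inputs: bool | None = None,
) -> dict:
    """OLS decode of the jPC-plane trajectories from the sensory feedback signals.

    Features are the delayed kinematic and muscle feedback as the network
    receives them; for the reach task the GO cue and static target inputs are
    included as well.  Returns pooled R2 over all planes plus per-plane R2.
    """
    if include_task_inputs is None:
        include_task_inputs = task.task == "reach"
    conds = (
        task.analysis_conditions
        if task.analysis_conditions is not None
        else np.arange(task.n_conditions)
    )
    feats = [batch.fb_x, batch.fb_m]
    if include_task_inputs and task.n_task_inputs:
        feats.append(task.task_input)
    F = np.concatenate(feats, axis=2)
    Xf = np.concatenate([F[c, steps[c]] for c in conds], axis=0)  # (C*L, nf)
    k, C, L = result.x_red.shape
    Y = result.x_red.reshape(k, C * L).T  # (C*L, k)
    A = np.concatenate([Xf, np.ones((len(Xf), 1))], axis=1)
    coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
    resid = Y - A @ coef
    sst_all = np.sum((Y - Y.mean(axis=0)) ** 2)
    pooled = 1.0 - float(np.sum(resid**2) / sst_all)
    per_plane = []
    for Q in result.plane_bases:
        Yp = Y @ Q
        Rp = resid @ Q
        sst = np.sum((Yp - Yp.mean(axis=0)) ** 2)
        per_plane.append(1.0 - float(np.sum(Rp**2) / sst))
    return {"pooled": pooled, "per_plane": per_plane}


def current_ratio(weights: Weights, batch: TrialBatch) -> dict[str, np.ndarray]:
    """Intrinsic-vs-sensory drive comparison for every input-layer unit.

    ``weight_ratio``: norm of the unit's recurrent weight row over the norm of
    its sensory weight row.  ``current_ratio``: the same ratio after weighting
    each source by the mean norm of its activity vector — the actual currents
    W E[.] delivered to the unit.  A current ratio near 0.5 means the sensory
    drive is about twice the intrinsic drive.
    """
    wr_rec = np.linalg.norm(weights.w_hh, axis=1)
    wr_sen = np.linalg.norm(weights.w_sh, axis=1)
    e_h = float(np.mean(np.linalg.norm(batch.h, axis=2)))
    e_s = float(np.mean(np.linalg.norm(batch.inputs, axis=2)))
    with np.errstate(divide="ignore", invalid="ignore"):
        weight_ratio = np.where(wr_sen > 0, wr_rec / wr_sen, 0.0)
        cr = np.where(wr_sen * e_s > 0, (wr_rec * e_h) / (wr_sen * e_s), 0.0)
    return {"weight_ratio": weight_ratio, "current_ratio": cr}


def run_task_experiment(
    task_name: str,
    recurrent: bool = True,
    seed: int = 0,
    scale: ScaleConfig = DESK_SCALE,
    feedback: str = "joint",
    init: str = "uniform",
    delay: float = 0.050,
    run_tme: bool = True,
    run_downsample: bool = True,
    task_kwargs: dict | None = None,
) -> ExperimentReport:
    """Train a controller on one task and run the complete dynamics analysis."""
    arm = ArmParams()
    muscles = MuscleParams()
    task = make_task(task_name, **(task_kwargs or {}))
    params = scale.network_params(recurrent=recurrent, init=init, delay=delay)
    result = train(
        task, params, scale.train_config(), muscles, arm, seed=seed, feedback=feedback
    )
    batch = evaluate(result.weights, params, task, muscles, arm, feedback=feedback)
    steps = analysis_window_steps(task, batch, arm, delay_steps=params.delay_steps)
    tensors = population_tensors(
        batch, task, arm, steps, cartesian_kinematics=(feedback == "cartesian")
    )

    jres = {name: jpca(t) for name, t in tensors.items()}
    tme_nulls: dict[str, TMENull] = {}
    if run_tme:
        for name in ("output", "input"):
            tme_nulls[name] = tme_test(
                tensors[name], n_surrogates=scale.n_surrogates, seed=seed,
                allow_small=tensors[name].shape[0] < 30,
            )
    downsample: dict[str, dict] = {}
    downsample_p: dict[str, dict] = {}
    if run_downsample:
        for name, k in (("muscle", 6), ("kinematics", 4)):
            n_sig = tensors[name].shape[0]
            dist = downsample_compare(
                tensors["output"], min(k, n_sig), n_iter=scale.n_downsample, seed=seed,
                softnorm=5e-4, n_components=jres[name].x_red.shape[0],
            )
            downsample[name] = dist
            downsample_p[name] = {
                "p_constrained": empirical_p_below(
                    dist["r2_constrained"], jres[name].r2_constrained
                ),
                "p_unconstrained": empirical_p_below(
                    dist["r2_unconstrained"], jres[name].r2_unconstrained
                ),
            }
    decode = decode_planes_from_feedback(jres["output"], batch, task, steps)
    return ExperimentReport(
        task=task_name,
        recurrent=recurrent,
        seed=seed,
        config={
            "n_units": scale.n_units,
            "lr": scale.lr,
            "max_epochs": scale.max_epochs,
            "feedback": feedback,
            "init": init,
            "delay": delay,
        },
        jpca_results=jres,
        tme_nulls=tme_nulls,
        downsample=downsample,
        downsample_p=downsample_p,
        decode_r2=decode,
        training_converged=result.converged,
    )


def endpoint_error(
    batch: TrialBatch, task: TaskBatch, arm: ArmParams, final_steps: int = 10
) -> float:
    """Mean hand distance (m) from the goal over the last ``final_steps`` samples."""
    hand = hand_position(batch.x, arm)
    goal = hand_position(task.x_star[:, -1], arm)
    err = np.linalg.norm(hand[:, -final_steps:] - goal[:, None, :], axis=2)
    return float(err.mean())


def noise_robustness(
    task_name: str,
    feedback_modes=("continuous", "pulse"),
    noise_levels=(0.0, 0.2, 0.4, 0.8),
    seed: int = 0,
    scale: ScaleConfig = DESK_SCALE,
    n_repeats: int = 5,
) -> dict:
    """Endpoint-error curves vs motor-noise level for differently fed-back controllers.

    A separate controller is trained per feedback mode *without* noise; at
    test time multiplicative Gaussian noise (variance = level x command^2)
    corrupts the motor commands.  Pulse mode passes feedback only for the
    first 200 ms after the perturbation; ``none`` removes feedback entirely
    (reach task, where the goal arrives via task inputs).
    """
    arm = ArmParams()
    muscles = MuscleParams()
    task = make_task(task_name)
    curves: dict[str, list[float]] = {}
    for mode in feedback_modes:
        params = scale.network_params(recurrent=True)
        result = train(
            task, params, scale.train_config(), muscles, arm, seed=seed, feedback_mode=mode
        )
        errs = []
        for level in noise_levels:
            trial_errs = []
            for rep in range(n_repeats if level > 0 else 1):
                rng = np.random.default_rng((seed + 1) * 10_000 + rep)
                batch = evaluate(
                    result.weights, params, task, muscles, arm,
                    feedback_mode=mode, noise_level=level, rng=rng,
                )
                trial_errs.append(endpoint_error(batch, task, arm))
            errs.append(float(np.mean(trial_errs)))
        curves[mode] = errs
    return {"noise_levels": list(noise_levels), "endpoint_error": curves}


def delay_sweep(
    delays=(0.0, 0.050, 0.100),
    n_seeds: int = 3,
    task_name: str = "posture",
    recurrent: bool = True,
    scale: ScaleConfig = DESK_SCALE,
) -> dict:
    """Constrained/unconstrained fits and top-plane frequency vs sensory delay.

    The posture analysis window shifts with the delay (dynamics cannot change
    before feedback about the load arrives); reach windows are not shifted
    because the GO cue, not feedback, initiates the movement.
    """
    arm = ArmParams()
    muscles = MuscleParams()
    out = {"delays": list(delays), "r2_constrained": [], "r2_unconstrained": [],
           "top_frequency_hz": [], "converged": []}
    for delay in delays:
        r2c, r2u, fr, conv = [], [], [], []
        for s in range(n_seeds):
            task = make_task(task_name)
            params = scale.network_params(recurrent=recurrent, delay=delay)
            result = train(task, params, scale.train_config(), muscles, arm, seed=s)
            batch = evaluate(result.weights, params, task, muscles, arm)
            shift = params.delay_steps if task.task == "posture" else 5
            steps = analysis_window_steps(task, batch, arm, delay_steps=shift)
            tensors = population_tensors(batch, task, arm, steps)
            res = jpca(tensors["output"])
            r2c.append(res.r2_constrained)
            r2u.append(res.r2_unconstrained)
            fr.append(res.plane_frequencies[0])
            conv.append(result.converged)
        out["r2_constrained"].append(float(np.mean(r2c)))
        out["r2_unconstrained"].append(float(np.mean(r2u)))
        out["top_frequency_hz"].append(float(np.mean(fr)))
        out["converged"].append(all(conv))
    return out


def cartesian_variant(
    task_name: str,
    init: str = "uniform",
    seed: int = 0,
    scale: ScaleConfig = DESK_SCALE,
    **kwargs,
) -> ExperimentReport:
    """Identical pipeline with cartesian hand-position/velocity feedback."""
    return run_task_experiment(
        task_name, recurrent=True, seed=seed, scale=scale,
        feedback="cartesian", init=init, **kwargs,
    )
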