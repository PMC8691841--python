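"""Synthetic population tensors and spike fixtures with known ground truth.

``planted_rotation_population`` builds units x conditions x time tensors
whose latent dynamics are exactly a block-diagonal skew-symmetric system
(pure rotations at chosen frequencies, optionally plus a symmetric expansion
mode), projected to the units through a random orthonormal loading with
additive white noise.  Because the generating dynamics matrix is known, the
rotational-dynamics analyses can be validated end to end: frequency
recovery, constrained/unconstrained fit behaviour, surrogate-test power.

Conditions share the same latent dynamics and differ only in their initial
phase and amplitude on each plane — the "initial conditions" picture of
condition structure in population dynamics.

``smooth_spikes`` converts spike timestamps to rates on the 10 ms grid with
a symmetric Gaussian kernel (analysis) or a causal half-Gaussian (display),
both area-normalized so a single spike integrates to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from armdyn.jpca import PopulationTensor


@dataclass
class PlantedDynamicsSpec:
    """Ground-truth generator settings.

    ``frequencies`` (Hz) and per-plane ``amplitudes`` define the rotation
    planes; ``expansion_gain`` (1/s) adds one symmetric (outward-spiraling)
    latent dimension when nonzero; ``noise_sd`` is the SD of iid additive
    noise per unit/sample.
    """

    n_units: int = 60
    n_conditions: int = 8
    n_steps: int = 30
    frequencies: tuple = (2.0, 0.5)
    amplitudes: tuple | None = None
    expansion_gain: float = 0.0
    expansion_amplitude: float = 1.0
    noise_sd: float = 0.0
    dt: float = 0.010
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.frequencies):
            raise ValueError("plane frequencies must be nonnegative")
        n_latent = 2 * len(self.frequencies) + (1 if self.expansion_gain else 0)
        if self.n_units < n_latent:
            raise ValueError("need at least as many units as latent dimensions")
        if self.amplitudes is None:
            self.amplitudes = tuple(1.0 for _ in self.frequencies)


def planted_rotation_population(spec: PlantedDynamicsSpec) -> tuple[PopulationTensor, dict]:
    """Generate a tensor with planted rotational latents; return it with ground truth.

    Latents follow z' = S z with S block-diagonal skew-symmetric at the
    requested angular frequencies (integrated exactly via per-step rotation
    matrices), plus an optional scalar expansion mode z' = g z.  Each
    condition gets a random initial phase and amplitude; latents are mapped
    to units by a random orthonormal loading Q, and iid Gaussian noise is
    added.  Ground truth contains S, Q and the noiseless latents.
    """
    rng = np.random.default_rng(spec.seed)
    P = len(spec.frequencies)
    n_latent = 2 * P + (1 if spec.expansion_gain else 0)
    N, C, T = spec.n_units, spec.n_conditions, spec.n_steps

    S = np.zeros((n_latent, n_latent))
    for p, f in enumerate(spec.frequencies):
        w = 2 * np.pi * f
        S[2 * p, 2 * p + 1] = w
        S[2 * p + 1, 2 * p] = -w
    if spec.expansion_gain:
        S[-1, -1] = spec.expansion_gain

    t = spec.dt * np.arange(T)
    z = np.zeros((n_latent, C, T))
    for p, f in enumerate(spec.frequencies):
        w = 2 * np.pi * f
        phase = rng.uniform(0, 2 * np.pi, size=C)
        amp = spec.amplitudes[p] * (0.5 + rng.uniform(size=C))
        z[2 * p] = amp[:, None] * np.cos(w * t[None, :] + phase[:, None])
        z[2 * p + 1] = amp[:, None] * np.sin(w * t[None, :] + phase[:, None])
    if spec.expansion_gain:
        sign = rng.choice([-1.0, 1.0], size=C)
        amp = spec.expansion_amplitude * (0.5 + rng.uniform(size=C))
        z[-1] = sign[:, None] * amp[:, None] * np.exp(spec.expansion_gain * t[None, :])

    Q = np.linalg.qr(rng.standard_normal((N, n_latent)))[0]
    data = np.einsum("nl,lct->nct", Q, z)
    if spec.noise_sd > 0:
        data = data + spec.noise_sd * rng.standard_normal(data.shape)
    truth = {"S": S, "loading": Q, "latents": z}
    return PopulationTensor(data, spec.dt, kind="network"), truth


def smooth_spikes(
    timestamps,
    t_stop: float,
    kernel_sd: float = 0.030,
    dt: float = 0.010,
    causal: bool = False,
) -> np.ndarray:
    """Kernel rate estimate of spike timestamps on the regular time grid.

    ``timestamps`` is an array of spike times (s) for one unit/trial, or a
    sequence of such arrays (averaged, e.g. trials).  The symmetric Gaussian
    kernel (SD ``kernel_sd``) is the analysis default; the causal
    half-Gaussian uses only past spikes, so the rate is zero strictly before
    the first spike.  Both integrate to one per spike, so values are in
    spikes per second.
    """
    if kernel_sd <= 0:
        raise ValueError("kernel SD must be positive")
    grid = np.arange(0.0, t_stop + dt / 2, dt)
    if isinstance(timestamps, np.ndarray) and timestamps.ndim == 1:
        trials = [timestamps.astype(float)]
    elif len(timestamps) == 0 or np.isscalar(timestamps[0]):
        trials = [np.asarray(timestamps, dtype=float)]
    else:
        trials = [np.asarray(ts, dtype=float) for ts in timestamps]
    rate = np.zeros_like(grid)
    for ts in trials:
        if ts.size and (ts.min() < 0 or ts.max() > t_stop):
            raise ValueError("spike timestamps outside trial bounds")
        if ts.size == 0:
            continue
        delta = grid[None, :] - ts[:, None]
        kern = np.exp(-0.5 * (delta / kernel_sd) ** 2) / (kernel_sd * np.sqrt(2 * np.pi))
        if causal:
            kern = np.where(delta >= 0, 2.0 * kern, 0.0)
        rate += kern.sum(axis=0)
    return rate / len(trials)
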