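"""Serialization: weight checkpoints (HDF5 + JSON metadata), tidy trial CSV, tensors.

Kept deliberately thin — every artifact is reproducible from a seed, so
files exist for inspection and hand-off, not as the system of record.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np
import pandas as pd

from armdyn.controller import NetworkParams, Weights, _FIELDS
from armdyn.jpca import PopulationTensor
from armdyn.training import TrialBatch


def save_weights(path, weights: Weights, params: NetworkParams, seed: int | None = None) -> None:
    """Weight checkpoint with a JSON metadata block (seed + architecture params)."""
    meta = {"seed": seed, "params": asdict(params)}
    with h5py.File(path, "w") as fh:
        g = fh.create_group("weights")
        for f in _FIELDS:
            g.create_dataset(f, data=getattr(weights, f))
        fh.attrs["metadata"] = json.dumps(meta, sort_keys=True)


def load_weights(path) -> tuple[Weights, NetworkParams, int | None]:
    with h5py.File(path, "r") as fh:
        arrays = {f: np.asarray(fh["weights"][f]) for f in _FIELDS}
        meta = json.loads(fh.attrs["metadata"])
    return Weights(**arrays), NetworkParams(**meta["params"]), meta["seed"]


def trials_to_frame(batch: TrialBatch) -> pd.DataFrame:
    """Tidy per-step kinematics and muscle activity: one row per (condition, t)."""
    C, T, _ = batch.x.shape
    dt = batch.task.dt if batch.task is not None else 0.010
    cond = np.repeat(np.arange(C), T)
    t = np.tile(dt * np.arange(T), C)
    x = batch.x.reshape(C * T, 4)
    m = batch.m.reshape(C * T, 6)
    data = {
        "condition": cond,
        "t": t,
        "theta_sho": x[:, 1],
        "theta_elb": x[:, 0],
        "omega_sho": x[:, 3],
        "omega_elb": x[:, 2],
    }
    for i in range(6):
        data[f"m{i + 1}"] = m[:, i]
    return pd.DataFrame(data)


def save_tensor(path, tensor: PopulationTensor, name: str = "tensor") -> None:
    with h5py.File(path, "a") as fh:
        if name in fh:
            del fh[name]
        g = fh.create_group(name)
        g.create_dataset("data", data=tensor.data)
        g.create_dataset("times", data=tensor.times)
        g.attrs["dt"] = tensor.dt
        g.attrs["kind"] = tensor.kind


def planes_to_frame(result) -> pd.DataFrame:
    """jPC-plane trajectories as tidy CSV-ready rows (plane, condition, t, u, v)."""
    k, C, T = result.x_red.shape
    rows = []
    for p, Q in enumerate(result.plane_bases):
        proj = np.einsum("kj,kct->jct", Q, result.x_red)  # (2, C, T)
        for c in range(C):
            for t in range(T):
                rows.append((p, c, t, proj[0, c, t], proj[1, c, t]))
    return pd.DataFrame(rows, columns=["plane", "condition", "t", "u", "v"])


def tme_report(null) -> dict:
    """JSON-ready digest of a TME hypothesis test."""
    q = np.percentile
    return {
        "n_surrogates": null.n_surrogates,
        "seed": null.seed,
        "observed": {
            "constrained": null.observed_constrained,
            "unconstrained": null.observed_unconstrained,
        },
        "surrogate_constrained": {
            "median": float(np.median(null.surrogate_constrained)),
            "iqr": [float(q(null.surrogate_constrained, 25)),
                    float(q(null.surrogate_constrained, 75))],
        },
        "p_constrained": null.p_constrained,
        "p_unconstrained": null.p_unconstrained,
    }


def load_tensor(path, name: str = "tensor") -> PopulationTensor:
    with h5py.File(path, "r") as fh:
        g = fh[name]
        return PopulationTensor(
            np.asarray(g["data"]), float(g.attrs["dt"]), str(g.attrs["kind"]),
            np.asarray(g["times"]),
        )
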