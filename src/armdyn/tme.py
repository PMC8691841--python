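"""Tensor-maximum-entropy (TME) surrogate nulls for rotational structure.

The null hypothesis: apparent rotational dynamics are a byproduct of the
primary features of the data — broad condition tuning, temporal smoothness
and shared variability across units — rather than an emergent population
property.  TME builds the maximum-entropy Gaussian distribution over
units x conditions x time tensors whose *expected* covariance along each
tensor mode matches the observed mode covariances, while leaving all
cross-mode interactions unconstrained.  Surrogates drawn from it share the
observed single-mode statistics but carry no built-in rotational structure.

Implementation: eigendecompose each mode covariance; the maximum-entropy
covariance is diagonal in the Kronecker product of the mode eigenbases with
spectrum ``s_ijk = 1 / (2 (lam_n_i + lam_c_j + lam_t_k))`` where the
Lagrange multipliers ``lam`` are found by minimizing the convex dual of the
entropy objective (L-BFGS with analytic gradients, positivity enforced via a
log reparametrization).  Sampling is then three mode-products of a scaled
white-noise tensor.

The hypothesis test runs the same dynamical fit on each surrogate and
reports add-one-smoothed p-values: p = (1 + #{surrogate >= observed}) / (n+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from armdyn.jpca import (
    PopulationTensor,
    derivative_pairs,
    fit_dynamics,
    preprocess,
    reduce_dims,
)

EIG_FLOOR = 1e-10


@dataclass
class ModeCovariances:
    """Mode-wise covariances of a (grand-mean-removed) data tensor."""

    unit: np.ndarray  # (N, N)
    condition: np.ndarray  # (C, C)
    time: np.ndarray  # (T, T)
    grand_mean: float

    def shapes(self) -> tuple[int, int, int]:
        return self.unit.shape[0], self.condition.shape[0], self.time.shape[0]


@dataclass
class TMENull:
    """Observed statistics, surrogate distributions and p-values of the TME test."""

    n_surrogates: int
    seed: int
    observed_constrained: float
    observed_unconstrained: float
    surrogate_constrained: np.ndarray
    surrogate_unconstrained: np.ndarray
    p_constrained: float
    p_unconstrained: float


def mode_covariances(data: np.ndarray) -> ModeCovariances:
    """Scatter matrices along each tensor mode after removing the grand mean.

    Computed as unnormalized scatter (sums of outer products over the other
    two modes), so the three matrices share the same trace — the total sum of
    squares — which the maximum-entropy construction requires.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected a units x conditions x time tensor")
    mu = float(data.mean())
    Z = data - mu
    N, C, T = Z.shape
    Zn = Z.reshape(N, C * T)
    Zc = np.moveaxis(Z, 1, 0).reshape(C, N * T)
    Zt = np.moveaxis(Z, 2, 0).reshape(T, N * C)
    return ModeCovariances(
        unit=Zn @ Zn.T, condition=Zc @ Zc.T, time=Zt @ Zt.T, grand_mean=mu
    )


def _floored_eigh(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(S)
    return np.maximum(vals, EIG_FLOOR), vecs


def fit_max_entropy(cov: ModeCovariances, tol: float = 1e-9) -> dict:
    """Solve for the Lagrange multipliers of the maximum-entropy tensor distribution.

    Returns the mode eigenbases, the Kronecker spectrum ``s`` (N, C, T) and
    diagnostics.  Raises if the optimizer fails to reach the constraint set.
    """
    dn, Un = _floored_eigh(cov.unit)
    dc, Uc = _floored_eigh(cov.condition)
    dt_, Ut = _floored_eigh(cov.time)
    # flooring can desynchronize the traces; restore the shared total power
    target = np.mean([dn.sum(), dc.sum(), dt_.sum()])
    dn = dn * (target / dn.sum())
    dc = dc * (target / dc.sum())
    dt_ = dt_ * (target / dt_.sum())
    N, C, T = len(dn), len(dc), len(dt_)
    d_all = np.concatenate([dn, dc, dt_])

    # heuristic start: exact for white tensors, good scale generally
    other = np.array([C * T] * N + [N * T] * C + [N * C] * T, dtype=float)
    x0 = np.log(other / (6.0 * d_all))

    def split(lam):
        return lam[:N], lam[N : N + C], lam[N + C :]

    def objective(nu):
        lam = np.exp(nu)
        ln, lc, lt = split(lam)
        ssum = ln[:, None, None] + lc[None, :, None] + lt[None, None, :]
        f = float(lam @ d_all - 0.5 * np.log(ssum).sum())
        marg_n = 0.5 * (1.0 / ssum).sum(axis=(1, 2))
        marg_c = 0.5 * (1.0 / ssum).sum(axis=(0, 2))
        marg_t = 0.5 * (1.0 / ssum).sum(axis=(0, 1))
        grad = (d_all - np.concatenate([marg_n, marg_c, marg_t])) * lam
        return f, grad

    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-15, "gtol": tol * max(1.0, target)},
    )
    lam = np.exp(res.x)
    ln, lc, lt = split(lam)
    ssum = ln[:, None, None] + lc[None, :, None] + lt[None, None, :]
    s = 0.5 / ssum
    # constraint violation: relative error of the marginal eigenvalue sums
    marg = np.concatenate([s.sum(axis=(1, 2)), s.sum(axis=(0, 2)), s.sum(axis=(0, 1))])
    rel_err = float(np.max(np.abs(marg - d_all) / (d_all + EIG_FLOOR)))
    if rel_err > 0.05:
        raise RuntimeError(
            f"maximum-entropy fit did not reach the covariance constraints "
            f"(relative error {rel_err:.3g}); optimizer status: {res.message}"
        )
    return {
        "bases": (Un, Uc, Ut),
        "spectrum": s,
        "eigenvalues": (dn, dc, dt_),
        "rel_err": rel_err,
        "grand_mean": cov.grand_mean,
    }


def sample_surrogates(
    cov: ModeCovariances, n: int, seed: int = 0, fit: dict | None = None
) -> np.ndarray:
    """Draw ``n`` surrogate tensors (n, N, C, T) from the maximum-entropy distribution."""
    if fit is None:
        fit = fit_max_entropy(cov)
    Un, Uc, Ut = fit["bases"]
    s = fit["spectrum"]
    N, C, T = s.shape
    rng = np.random.default_rng(seed)
    sqrt_s = np.sqrt(s)
    out = np.empty((n, N, C, T))
    for start in range(0, n, 128):  # chunked to bound peak memory
        stop = min(start + 128, n)
        z = rng.standard_normal((stop - start, N, C, T)) * sqrt_s[None]
        y = np.einsum("ni,sijk->snjk", Un, z)
        y = np.einsum("cj,snjk->snck", Uc, y)
        out[start:stop] = np.einsum("tk,snck->snct", Ut, y)
    return out + fit["grand_mean"]


def _fit_r2(data: np.ndarray, dt: float, n_components: int) -> tuple[float, float]:
    """Constrained and unconstrained dynamical-fit R2 of an already-normalized tensor."""
    tensor = PopulationTensor(data - data.mean(axis=1, keepdims=True), dt)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        x_red, _, _ = reduce_dims(tensor, n_components)
    xs, xd = derivative_pairs(x_red, dt)
    _, r2c = fit_dynamics(xs, xd, constrain=True)
    _, r2u = fit_dynamics(xs, xd, constrain=False)
    return r2c, r2u


def tme_test(
    tensor: PopulationTensor,
    n_surrogates: int = 1000,
    seed: int = 0,
    softnorm: float | None = None,
    n_components: int = 6,
    allow_small: bool = False,
) -> TMENull:
    """TME hypothesis test for rotational structure in a population tensor.

    The tensor is preprocessed exactly as for the observed-data fit; mode
    covariances are taken from the preprocessed tensor and each surrogate is
    run through the same reduction and dynamical fits.  Populations below 30
    units are refused (the test is unreliable there — use the down-sampling
    control instead) unless ``allow_small`` is set.
    """
    N = tensor.shape[0]
    if N < 30 and not allow_small:
        raise ValueError(
            "TME testing is unreliable below 30 units; pass allow_small=True to override"
        )
    if n_surrogates < 100:
        warnings.warn("fewer than 100 surrogates gives coarse p-value resolution", RuntimeWarning)
    prepped = preprocess(tensor, softnorm)
    r2c_obs, r2u_obs = _fit_r2(prepped.data, prepped.dt, n_components)
    cov = mode_covariances(prepped.data)
    fit = fit_max_entropy(cov)
    surr = sample_surrogates(cov, n_surrogates, seed=seed, fit=fit)
    r2c = np.empty(n_surrogates)
    r2u = np.empty(n_surrogates)
    for i in range(n_surrogates):
        if np.allclose(surr[i], prepped.data):
            raise RuntimeError("surrogate identical to observed tensor; sampling is broken")
        r2c[i], r2u[i] = _fit_r2(surr[i], prepped.dt, n_components)
    p_c = (1 + int(np.sum(r2c >= r2c_obs))) / (n_surrogates + 1)
    p_u = (1 + int(np.sum(r2u >= r2u_obs))) / (n_surrogates + 1)
    return TMENull(
        n_surrogates=n_surrogates,
        seed=seed,
        observed_constrained=r2c_obs,
        observed_unconstrained=r2u_obs,
        surrogate_constrained=r2c,
        surrogate_unconstrained=r2u,
        p_constrained=p_c,
        p_unconstrained=p_u,
    )
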