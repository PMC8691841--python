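"""Dynamical-fit machinery: preprocessing, reduction, skew fits, planes, down-sampling."""

import numpy as np
import pytest
from scipy.optimize import minimize

from armdyn.jpca import (
    PopulationTensor,
    _skew_basis,
    derivative_pairs,
    downsample_compare,
    fit_dynamics,
    jpca,
    planes_and_frequencies,
    preprocess,
    reduce_dims,
)
from armdyn.synth import PlantedDynamicsSpec, planted_rotation_population


def _random_tensor(n=12, c=5, t=20, seed=0):
    rng = np.random.default_rng(seed)
    # smooth-ish random traces
    data = np.cumsum(rng.normal(size=(n, c, t)), axis=2)
    return PopulationTensor(data, 0.01)


def test_preprocess_removes_condition_independent_signal():
    rng = np.random.default_rng(1)
    data = np.tile(rng.normal(size=(4, 1, 30)), (1, 6, 1))  # identical in every condition
    out = preprocess(PopulationTensor(data, 0.01), softnorm=5e-4)
    assert np.allclose(out.data, 0.0)


def test_preprocess_exact_normalization_at_zero_constant():
    t = _random_tensor(seed=2)
    out = preprocess(t, softnorm=0.0)
    # before mean subtraction the range would be exactly 1; reconstruct it
    rng_ = t.data.max(axis=(1, 2)) - t.data.min(axis=(1, 2))
    normed = t.data / rng_[:, None, None]
    assert np.allclose(normed.max(axis=(1, 2)) - normed.min(axis=(1, 2)), 1.0)
    assert np.allclose(out.data, normed - normed.mean(axis=1, keepdims=True))


def test_preprocess_rejects_negative_constant():
    with pytest.raises(ValueError):
        preprocess(_random_tensor(), softnorm=-1e-3)


def test_reduction_variance_ordering_and_reconstruction():
    t = preprocess(_random_tensor(n=15, seed=3))
    x_red, basis, frac = reduce_dims(t, 6)
    N, C, T = t.shape
    X = t.data.reshape(N, C * T)
    # eigen-decomposition oracle: discarded variance = sum of trailing eigenvalues
    evals = np.sort(np.linalg.eigvalsh(X @ X.T))[::-1]
    recon = basis @ (basis.T @ X)
    assert np.allclose(np.sum((X - recon) ** 2), evals[6:].sum(), rtol=1e-8)
    var_by_comp = np.sum(x_red.reshape(6, -1) ** 2, axis=1)
    assert np.all(np.diff(var_by_comp) <= 1e-9)
    assert frac == pytest.approx(evals[:6].sum() / evals.sum())
    assert np.allclose(basis.T @ basis, np.eye(6), atol=1e-12)


def test_reduction_lossless_when_rank_six():
    rng = np.random.default_rng(4)
    lat = rng.normal(size=(6, 4, 25))
    Q = np.linalg.qr(rng.normal(size=(20, 6)))[0]
    data = np.einsum("nl,lct->nct", Q, lat)
    data -= data.mean(axis=1, keepdims=True)
    t = PopulationTensor(data, 0.01)
    x_red, basis, frac = reduce_dims(t, 6)
    assert frac == pytest.approx(1.0)


def test_skew_fit_recovers_exact_skew_system():
    rng = np.random.default_rng(5)
    B = _skew_basis(6)
    M0 = np.einsum("b,bij->ij", rng.normal(size=15), B)
    X = rng.normal(size=(6, 300))
    Xd = M0 @ X
    M, r2 = fit_dynamics(X, Xd, constrain=True)
    assert np.allclose(M, M0, atol=1e-8)
    assert r2 == pytest.approx(1.0, abs=1e-10)


def test_skew_fit_fails_on_pure_expansion():
    """Data from x_dot = a x (a > 0): the best rotation explains ~nothing."""
    rng = np.random.default_rng(6)
    X = rng.normal(size=(6, 400))
    Xd = 1.7 * X
    M, r2 = fit_dynamics(X, Xd, constrain=True)
    # brute-force optimizer over the 15 skew parameters confirms the ceiling
    B = _skew_basis(6)

    def loss(c):
        Mc = np.einsum("b,bij->ij", c, B)
        return np.sum((Xd - Mc @ X) ** 2)

    res = minimize(loss, np.zeros(15), method="L-BFGS-B")
    sse_closed = np.sum((Xd - M @ X) ** 2)
    assert sse_closed <= res.fun + 1e-6
    assert r2 < 0.05


def test_closed_form_matches_brute_force_on_random_instances():
    """50 random 6 x 200 instances: closed form == generic optimizer to 1e-6 Frobenius."""
    rng = np.random.default_rng(7)
    B = _skew_basis(6)
    for _ in range(50):
        X = rng.normal(size=(6, 200))
        Xd = rng.normal(size=(6, 200))
        M, _ = fit_dynamics(X, Xd, constrain=True)

        def loss_grad(c):
            Mc = np.einsum("b,bij->ij", c, B)
            R = Mc @ X - Xd
            return np.sum(R**2), 2 * np.einsum("bij,in,jn->b", B, R, X)

        res = minimize(loss_grad, np.zeros(15), jac=True, method="L-BFGS-B",
                       options={"gtol": 1e-12, "ftol": 1e-15})
        M_opt = np.einsum("b,bij->ij", res.x, B)
        assert np.linalg.norm(M - M_opt) < 1e-6


def test_unconstrained_always_at_least_constrained():
    for seed in range(5):
        t = preprocess(_random_tensor(seed=seed))
        x_red, _, _ = reduce_dims(t, 6)
        xs, xd = derivative_pairs(x_red, t.dt)
        _, r2u = fit_dynamics(xs, xd, constrain=False)
        _, r2c = fit_dynamics(xs, xd, constrain=True)
        assert r2u >= r2c - 1e-12


def test_skew_matrix_exactly_antisymmetric():
    t = preprocess(_random_tensor(seed=11))
    res = jpca(t, preprocessed=True)
    assert np.array_equal(res.m_skew, -res.m_skew.T)
    assert np.all(np.abs(np.real(np.linalg.eigvals(res.m_skew))) < 1e-10)


def test_plane_frequencies_of_known_rotation():
    m = np.zeros((6, 6))
    w = 2 * np.pi * 2.0
    m[0, 1], m[1, 0] = w, -w
    freqs, bases = planes_and_frequencies(m)
    assert freqs[0] == pytest.approx(2.0)
    assert np.allclose(freqs[1:], 0.0)
    # plane basis spans the e0/e1 plane
    span = bases[0] @ bases[0].T
    assert span[0, 0] == pytest.approx(1.0) and span[1, 1] == pytest.approx(1.0)


def test_zero_matrix_all_frequencies_zero():
    freqs, _ = planes_and_frequencies(np.zeros((6, 6)))
    assert np.allclose(freqs, 0.0)


def test_plane_vaf_bounded_by_pc_fraction():
    t = preprocess(_random_tensor(n=20, seed=9))
    res = jpca(t, preprocessed=True)
    assert np.all(res.plane_vaf >= 0)
    assert res.plane_vaf.sum() <= res.pc_variance_fraction + 1e-9


def test_derivative_respects_condition_boundaries():
    k, C, T = 2, 3, 5
    x = np.arange(k * C * T, dtype=float).reshape(k, C, T)
    xs, xd = derivative_pairs(x, 0.01)
    assert xs.shape == (k, C * (T - 1))
    assert np.allclose(xd, 100.0)  # within-condition increments only


def test_downsample_degenerate_full_population():
    spec = PlantedDynamicsSpec(n_units=10, n_conditions=4, n_steps=25, noise_sd=0.05)
    tensor, _ = planted_rotation_population(spec)
    full = jpca(tensor)
    dist = downsample_compare(tensor, 10, n_iter=5, seed=1)
    assert np.allclose(dist["r2_constrained"], full.r2_constrained)
    assert np.allclose(dist["r2_unconstrained"], full.r2_unconstrained)


def test_downsample_deterministic_given_seed():
    spec = PlantedDynamicsSpec(n_units=12, n_conditions=4, n_steps=20, noise_sd=0.1)
    tensor, _ = planted_rotation_population(spec)
    d1 = downsample_compare(tensor, 4, n_iter=8, seed=3)
    d2 = downsample_compare(tensor, 4, n_iter=8, seed=3)
    assert np.array_equal(d1["r2_constrained"], d2["r2_constrained"])
    with pytest.raises(ValueError):
        downsample_compare(tensor, 13, n_iter=2)
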