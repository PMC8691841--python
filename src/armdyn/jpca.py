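"""Rotational-dynamics analysis of population tensors (jPCA-style).

Pipeline: soft-normalize each unit by its activity range, subtract the
cross-condition mean at every time point, reduce to the top principal
components, and fit the linear dynamical system ``X_dot = M X`` by least
squares — once unconstrained and once with ``M`` restricted to the
skew-symmetric subspace, so that only pure rotations can be fit.  The
skew-symmetric matrix decomposes into orthogonal two-dimensional planes
(conjugate eigenvector pairs); eigenvalue magnitudes give the rotation
frequencies and each plane's variance accounted for (VAF) is measured
against the total variance of the preprocessed data.

The constrained/unconstrained R-squared pair, with surrogate or
down-sampling nulls, quantifies how rotational the population dynamics are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: soft-normalization constants by signal kind (range units of each kind)
SOFTNORM_BY_KIND = {
    "network": 5e-4,
    "spikes": 5.0,
    "muscle": 0.0,
    "kinematics": 0.0,
}

#: number of components retained by signal kind
N_COMPONENTS_BY_KIND = {
    "network": 6,
    "spikes": 6,
    "muscle": 4,
    "kinematics": 2,
}


@dataclass
class PopulationTensor:
    """units x conditions x time array with its time base and signal kind."""

    data: np.ndarray  # (N, C, T)
    dt: float = 0.010
    kind: str = "network"
    times: np.ndarray | None = None  # (T,) seconds, alignment-relative

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("population tensor must be units x conditions x time")
        if self.data.shape[2] < 2:
            raise ValueError("need at least two time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("population tensor contains non-finite values")
        if self.times is None:
            self.times = self.dt * np.arange(self.data.shape[2])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def window(self, t_start: float, t_stop: float) -> "PopulationTensor":
        """Sub-tensor with times in [t_start, t_stop] (inclusive, seconds)."""
        sel = (self.times >= t_start - 1e-9) & (self.times <= t_stop + 1e-9)
        if sel.sum() < 2:
            raise ValueError("analysis window contains fewer than two samples")
        return PopulationTensor(self.data[:, :, sel], self.dt, self.kind, self.times[sel])


@dataclass
class JPCAResult:
    """Output of the full analysis on one tensor."""

    x_red: np.ndarray           # (k, C, T) reduced trajectories
    basis: np.ndarray           # (N, k) principal-component basis
    m_best: np.ndarray          # (k, k) unconstrained dynamics matrix
    m_skew: np.ndarray          # (k, k) skew-symmetric dynamics matrix
    r2_constrained: float
    r2_unconstrained: float
    plane_frequencies: np.ndarray  # (k//2,) Hz, descending
    plane_vaf: np.ndarray          # (k//2,) fraction of total variance
    plane_bases: np.ndarray        # (k//2, k, 2) orthonormal plane bases in PC space
    pc_variance_fraction: float    # variance fraction captured by the k PCs
    total_variance: float


def preprocess(tensor: PopulationTensor, softnorm: float | None = None) -> PopulationTensor:
    """Soft-normalize per unit and remove the cross-condition mean at each time.

    Each unit's trace is divided by (its activity range over all conditions
    and times + ``softnorm``); a zero constant normalizes every active unit's
    range to exactly 1.  Subtracting the cross-condition mean removes the
    condition-independent signal, the standard preparation for rotational-
    dynamics fits.
    """
    if softnorm is None:
        softnorm = SOFTNORM_BY_KIND[tensor.kind]
    if softnorm < 0:
        raise ValueError("soft-normalization constant must be nonnegative")
    data = tensor.data
    rng_ = data.max(axis=(1, 2)) - data.min(axis=(1, 2))
    denom = rng_ + softnorm
    safe = np.where(denom > 0, denom, 1.0)
    out = data / safe[:, None, None]
    out = out - out.mean(axis=1, keepdims=True)
    return PopulationTensor(out, tensor.dt, tensor.kind, tensor.times)


def reduce_dims(
    tensor: PopulationTensor, n_components: int | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """PCA reduction of the (N, C*T) matrix to the top components.

    Returns ``(x_red (k, C, T), basis (N, k), variance_fraction)``.  If fewer
    than ``n_components`` informative dimensions exist, the available rank is
    kept and a warning is issued.
    """
    if n_components is None:
        n_components = N_COMPONENTS_BY_KIND[tensor.kind]
    N, C, T = tensor.shape
    X = tensor.data.reshape(N, C * T)
    # rows have zero mean after cross-condition mean subtraction; PCA = SVD
    U, s, _ = np.linalg.svd(X - X.mean(axis=1, keepdims=True), full_matrices=False)
    var = s**2
    rank = int(np.sum(var > var[0] * 1e-12)) if var.size else 0
    k = min(n_components, N, rank)
    if k < n_components:
        warnings.warn(
            f"requested {n_components} components but only {k} informative dimensions",
            RuntimeWarning,
        )
    basis = U[:, :k]
    x_red = (basis.T @ X).reshape(k, C, T)
    frac = float(var[:k].sum() / var.sum()) if var.sum() > 0 else 0.0
    return x_red, basis, frac


def _skew_basis(k: int) -> np.ndarray:
    """Orthogonal basis of the k x k skew-symmetric subspace, (k(k-1)/2, k, k)."""
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    B = np.zeros((len(pairs), k, k))
    for idx, (i, j) in enumerate(pairs):
        B[idx, i, j] = 1.0
        B[idx, j, i] = -1.0
    return B


def derivative_pairs(x_red: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """First-difference derivative within each condition.

    Returns (states (k, C*(T-1)), derivatives (k, C*(T-1))); the final sample
    of every condition is dropped so no difference spans a condition boundary.
    """
    k, C, T = x_red.shape
    xd = (x_red[:, :, 1:] - x_red[:, :, :-1]) / dt
    xs = x_red[:, :, :-1]
    return xs.reshape(k, C * (T - 1)), xd.reshape(k, C * (T - 1))


def fit_dynamics(
    x: np.ndarray, x_dot: np.ndarray, constrain: bool
) -> tuple[np.ndarray, float]:
    """Least-squares fit of ``x_dot = M x``; optionally restrict M to skew-symmetric.

    The unconstrained fit solves the normal equations directly; the
    constrained fit solves them over the skew-symmetric subspace (dimension
    k(k-1)/2).  R-squared compares the residual to the column-mean-removed
    derivative, so constrained and unconstrained values share a denominator.
    """
    k, n = x.shape
    if x_dot.shape != x.shape:
        raise ValueError("state and derivative matrices must have equal shapes")
    G = x @ x.T
    if constrain:
        B = _skew_basis(k)
        BX = np.einsum("bij,jn->bin", B, x)
        A = np.einsum("bin,cin->bc", BX, BX)
        rhs = np.einsum("bin,in->b", BX, x_dot)
        try:
            coef = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            warnings.warn("singular skew normal equations; using ridge fallback", RuntimeWarning)
            coef = np.linalg.solve(A + 1e-8 * np.trace(A) / len(A) * np.eye(len(A)), rhs)
        M = np.einsum("b,bij->ij", coef, B)
    else:
        try:
            M = np.linalg.solve(G, x @ x_dot.T).T
        except np.linalg.LinAlgError:
            warnings.warn("singular normal equations; using ridge fallback", RuntimeWarning)
            M = np.linalg.solve(G + 1e-8 * np.trace(G) / k * np.eye(k), x @ x_dot.T).T
    resid = x_dot - M @ x
    denom = np.sum((x_dot - x_dot.mean(axis=1, keepdims=True)) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / denom) if denom > 0 else 0.0
    return M, r2


def planes_and_frequencies(m_skew: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation planes of a skew-symmetric matrix, ranked by rotation speed.

    Returns ``(frequencies_hz (k//2,), plane_bases (k//2, k, 2))``.  Each
    plane is spanned by the (orthonormalized) real and imaginary parts of one
    conjugate eigenvector pair; the frequency is |eigenvalue| / 2 pi.  Ties
    and zero eigenvalues are broken by a stable (descending, order-preserving)
    sort.
    """
    if not np.allclose(m_skew, -m_skew.T, atol=1e-10):
        raise ValueError("matrix is not skew-symmetric")
    k = m_skew.shape[0]
    evals, evecs = np.linalg.eig(m_skew)
    omega = np.imag(evals)
    # one representative per conjugate pair (positive imaginary part, or zero)
    order = np.argsort(-np.abs(omega), kind="stable")
    used = np.zeros(k, dtype=bool)
    freqs, bases = [], []
    for idx in order:
        if used[idx] or len(freqs) == k // 2:
            continue
        lam = omega[idx]
        v = evecs[:, idx]
        # mark this eigenvalue and its conjugate partner as used
        used[idx] = True
        partner = np.where(~used & np.isclose(omega, -lam) )[0]
        if partner.size:
            used[partner[0]] = True
        a, b = np.real(v), np.imag(v)
        Q, _ = np.linalg.qr(np.stack([a, b], axis=1))
        if Q.shape[1] < 2:  # degenerate (zero) plane: complete arbitrarily but deterministically
            comp = np.eye(k)[:, : 2]
            Q, _ = np.linalg.qr(np.concatenate([Q, comp], axis=1))
            Q = Q[:, :2]
        freqs.append(abs(lam) / (2 * np.pi))
        bases.append(Q[:, :2])
    return np.asarray(freqs), np.asarray(bases)


def jpca(
    tensor: PopulationTensor,
    softnorm: float | None = None,
    n_components: int | None = None,
    preprocessed: bool = False,
) -> JPCAResult:
    """Full analysis: preprocess, reduce, fit both dynamical systems, extract planes."""
    prepped = tensor if preprocessed else preprocess(tensor, softnorm)
    x_red, basis, frac = reduce_dims(prepped, n_components)
    xs, xd = derivative_pairs(x_red, prepped.dt)
    m_best, r2_u = fit_dynamics(xs, xd, constrain=False)
    m_skew, r2_c = fit_dynamics(xs, xd, constrain=True)
    freqs, plane_bases = planes_and_frequencies(m_skew)
    total_var = float(np.sum(prepped.data**2))
    k, C, T = x_red.shape
    Xr = x_red.reshape(k, C * T)
    vaf = np.array(
        [float(np.sum((Q.T @ Xr) ** 2)) / total_var for Q in plane_bases]
    ) if total_var > 0 else np.zeros(len(plane_bases))
    return JPCAResult(
        x_red=x_red,
        basis=basis,
        m_best=m_best,
        m_skew=m_skew,
        r2_constrained=r2_c,
        r2_unconstrained=r2_u,
        plane_frequencies=freqs,
        plane_vaf=vaf,
        plane_bases=plane_bases,
        pc_variance_fraction=frac,
        total_variance=total_var,
    )


def downsample_compare(
    tensor: PopulationTensor,
    k_signals: int,
    n_iter: int = 1000,
    seed: int = 0,
    softnorm: float | None = None,
    n_components: int | None = None,
) -> dict[str, np.ndarray]:
    """Distribution of fit quality for random k-unit subsets of a population.

    For each iteration, sample ``k_signals`` units without replacement, run
    the full analysis, and record both R-squared values.  The empirical
    p-value of a comparison value is the fraction of iterations at or below
    it.
    """
    N = tensor.shape[0]
    if k_signals > N:
        raise ValueError("cannot sample more units than the population has")
    rng = np.random.default_rng(seed)
    r2c = np.empty(n_iter)
    r2u = np.empty(n_iter)
    for i in range(n_iter):
        idx = rng.choice(N, size=k_signals, replace=False)
        sub = PopulationTensor(tensor.data[idx], tensor.dt, tensor.kind, tensor.times)
        res = jpca(sub, softnorm=softnorm, n_components=n_components)
        r2c[i] = res.r2_constrained
        r2u[i] = res.r2_unconstrained
    return {"r2_constrained": r2c, "r2_unconstrained": r2u}


def empirical_p_below(samples: np.ndarray, value: float) -> float:
    """Fraction of null samples at or below ``value`` (one-sided, 'worse than null')."""
    samples = np.asarray(samples)
    return float(np.mean(samples <= value))
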