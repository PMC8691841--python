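"""Planar two-link arm with six lumped muscle actuators.

The arm moves in a horizontal plane (no gravity) and is driven by joint
torques produced by six muscles: a flexor/extensor pair at the shoulder, a
pair at the elbow, and a biarticular pair spanning both joints.  Muscle force
is activation x maximal force, scaled by force-length (F-L) and
force-velocity (F-V) gain curves evaluated at the muscle's normalized length
and velocity; lengths and velocities follow linearly from the joint
configuration through a constant moment-arm matrix.

State-vector convention (fixed throughout the package)::

    x = [theta_elb, theta_sho, omega_elb, omega_sho]   (rad, rad/s)

Two-joint vectors such as torques are ordered (shoulder, elbow).  The
continuous rigid-body dynamics are discretized by forward Euler with
dt = 10 ms.

The module also provides the analytic Jacobians of the discrete step with
respect to the state and the muscle activations; these are what make the
simulation differentiable for backpropagation-through-time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# state-vector index mapping:  state layout [th_e, th_s, om_e, om_s]
# internal joint layout        [th_s, th_e, om_s, om_e]
_PERM = np.array([1, 0, 3, 2])


@dataclass
class ArmParams:
    """Rigid-body parameters of the planar arm (upper arm = link 1, forearm = link 2).

    Defaults are the standard planar-arm set from the optimal-control
    literature on human/monkey reaching; all lengths in metres, masses in kg,
    inertias (about each link's centre of mass) in kg m^2, viscosity in
    N m s/rad.
    """

    l1: float = 0.30
    l2: float = 0.33
    m1: float = 1.4
    m2: float = 1.0
    i1: float = 0.025
    i2: float = 0.045
    d1: float = 0.11
    d2: float = 0.16
    viscosity: float = 0.05
    dt: float = 0.010

    def __post_init__(self) -> None:
        for name in ("l1", "l2", "m1", "m2", "i1", "i2", "d1", "d2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"arm parameter {name} must be strictly positive")
        if not np.isclose(self.dt, 0.010):
            raise ValueError("integration step dt is fixed at 0.010 s")


def _default_moment_arms() -> np.ndarray:
    # rows: (sho flex, sho ext, elb flex, elb ext, biart flex, biart ext)
    # cols: (shoulder, elbow); metres.  Positive = flexion torque.
    return np.array(
        [
            [+0.020, 0.0],
            [-0.020, 0.0],
            [0.0, +0.020],
            [0.0, -0.020],
            [+0.015, +0.020],
            [-0.015, -0.020],
        ]
    )


@dataclass
class MuscleParams:
    """Six lumped muscles: constant moment arms plus smooth F-L / F-V gains.

    ``l0`` is the optimal-length scale used to normalize length excursions;
    ``ref_angles`` (shoulder, elbow, rad) is the posture at which every muscle
    sits at its optimal length.  F-L is a Gaussian of width ``fl_width`` around
    the optimum.  F-V is hyperbolic: force falls to zero at shortening
    velocity ``-fv_vmax`` (optimal lengths / s) and saturates at
    ``fv_max_lengthen`` for fast lengthening, with FV(0) = 1.
    """

    moment_arm: np.ndarray = field(default_factory=_default_moment_arms)
    f_max: np.ndarray = field(default_factory=lambda: np.full(6, 40.0))
    l0: float = 0.10
    fl_width: float = 0.3
    fv_vmax: float = 10.0
    fv_shorten_curv: float = 0.25
    fv_max_lengthen: float = 1.3
    fv_lengthen_scale: float = 1.0
    ref_angles: np.ndarray = field(default_factory=lambda: np.array([np.pi / 4, np.pi / 2]))

    def __post_init__(self) -> None:
        self.moment_arm = np.asarray(self.moment_arm, dtype=float)
        self.f_max = np.asarray(self.f_max, dtype=float)
        if self.moment_arm.shape != (6, 2):
            raise ValueError("moment-arm matrix must be 6 muscles x 2 joints")
        n_joints = (np.abs(self.moment_arm) > 0).sum(axis=1)
        if not (np.all(n_joints[:4] == 1) and np.all(n_joints[4:] == 2)):
            raise ValueError(
                "muscles 1-4 must be monoarticular (one nonzero moment arm), "
                "muscles 5-6 biarticular (two)"
            )


def _joint_view(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split state array (..., 4) into angles and velocities in (sho, elb) order."""
    th = x[..., [1, 0]]
    om = x[..., [3, 2]]
    return th, om


def muscle_gains(
    x: np.ndarray, muscles: MuscleParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """F-L and F-V gains and their derivatives w.r.t. normalized length/velocity.

    Returns ``(fl, fv, dfl, dfv)``, each shaped (..., 6).
    """
    th, om = _joint_view(np.asarray(x, dtype=float))
    A = muscles.moment_arm  # (6, 2)
    # normalized length: flexors (positive moment arm) shorten as the joint flexes
    lnorm = 1.0 - (th - muscles.ref_angles) @ A.T / muscles.l0
    vnorm = -om @ A.T / muscles.l0  # d lnorm / dt; negative = shortening

    w = muscles.fl_width
    fl = np.exp(-(((lnorm - 1.0) / w) ** 2))
    dfl = fl * (-2.0 * (lnorm - 1.0) / w**2)

    vmax = muscles.fv_vmax
    k = muscles.fv_shorten_curv
    g = muscles.fv_lengthen_scale
    fv = np.empty_like(vnorm)
    dfv = np.empty_like(vnorm)
    short = vnorm < 0
    vs = np.clip(vnorm, -vmax, 0.0)
    num = 1.0 + vs / vmax
    den = 1.0 - vs / (vmax * k)
    fv_s = num / den
    dfv_s = (1.0 / vmax / den) + num / den**2 / (vmax * k)
    dfv_s = np.where(vnorm <= -vmax, 0.0, dfv_s)
    vl = np.clip(vnorm, 0.0, None)
    amp = muscles.fv_max_lengthen - 1.0
    fv_l = muscles.fv_max_lengthen - amp * g / (g + vl)
    dfv_l = amp * g / (g + vl) ** 2
    fv[...] = np.where(short, fv_s, fv_l)
    dfv[...] = np.where(short, dfv_s, dfv_l)
    return fl, fv, dfl, dfv


def muscle_forces(m: np.ndarray, x: np.ndarray, muscles: MuscleParams) -> np.ndarray:
    """Per-muscle force (N): activation x F_max x FL x FV.  Shapes broadcast on (..., 6)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite arm state (integration blow-up?)")
    fl, fv, _, _ = muscle_gains(x, muscles)
    return np.asarray(m, dtype=float) * muscles.f_max * fl * fv


def muscle_torques(m: np.ndarray, x: np.ndarray, muscles: MuscleParams) -> np.ndarray:
    """Joint torques (shoulder, elbow) in N m produced by muscle activations ``m``."""
    forces = muscle_forces(m, x, muscles)
    return forces @ muscles.moment_arm


def _inertia_terms(x: np.ndarray, arm: ArmParams):
    th, om = _joint_view(x)
    the = th[..., 1]
    c2 = np.cos(the)
    s2 = np.sin(the)
    hcoef = arm.m2 * arm.l1 * arm.d2
    m11 = arm.i1 + arm.m1 * arm.d1**2 + arm.i2 + arm.m2 * (
        arm.l1**2 + arm.d2**2
    ) + 2.0 * hcoef * c2
    m12 = arm.i2 + arm.m2 * arm.d2**2 + hcoef * c2
    m22 = np.broadcast_to(arm.i2 + arm.m2 * arm.d2**2, m11.shape)
    # Coriolis / centripetal vector (enters as M th'' + c + B om = torque)
    oms, ome = om[..., 0], om[..., 1]
    c1 = -hcoef * s2 * (2.0 * oms * ome + ome**2)
    cc2 = hcoef * s2 * oms**2
    return m11, m12, m22, c1, cc2, s2, c2, hcoef


def _accel(x: np.ndarray, torque_joint: np.ndarray, arm: ArmParams):
    """Joint accelerations (sho, elb) plus cached terms for the Jacobian."""
    _, om = _joint_view(x)
    m11, m12, m22, c1, c2v, s2, c2, hcoef = _inertia_terms(x, arm)
    tau = torque_joint - np.stack([c1, c2v], axis=-1) - arm.viscosity * om
    det = m11 * m22 - m12 * m12
    if np.any(det <= 0):
        raise AssertionError("inertia matrix must be positive definite")
    a_s = (m22 * tau[..., 0] - m12 * tau[..., 1]) / det
    a_e = (m11 * tau[..., 1] - m12 * tau[..., 0]) / det
    return np.stack([a_s, a_e], axis=-1), (m11, m12, m22, det, s2, c2, hcoef)


def step_arm(
    x: np.ndarray,
    m: np.ndarray,
    muscles: MuscleParams,
    arm: ArmParams,
    load: np.ndarray | None = None,
) -> np.ndarray:
    """One forward-Euler step of the arm under muscle activations plus external load.

    ``load`` is the externally applied (shoulder, elbow) perturbation torque in
    N m (zero outside posture perturbations).
    """
    x = np.asarray(x, dtype=float)
    torque = muscle_torques(m, x, muscles)
    if load is not None:
        torque = torque + np.asarray(load, dtype=float)
    acc, _ = _accel(x, torque, arm)
    th, om = _joint_view(x)
    th_next = th + arm.dt * om
    om_next = om + arm.dt * acc
    out = np.concatenate([th_next, om_next], axis=-1)
    return out[..., _PERM]


def step_arm_jacobians(
    x: np.ndarray, m: np.ndarray, muscles: MuscleParams, arm: ArmParams,
    load: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic Jacobians of the Euler step: (d x'/d x, d x'/d m).

    Shapes (..., 4, 4) and (..., 4, 6), in the package state layout.  Used by
    backpropagation-through-time; validated against finite differences in the
    test suite.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    A = muscles.moment_arm
    fl, fv, dfl, dfv = muscle_gains(x, muscles)
    forces = m * muscles.f_max * fl * fv
    torque = forces @ A
    if load is not None:
        torque = torque + np.asarray(load, dtype=float)
    acc, (m11, m12, m22, det, s2, c2, hcoef) = _accel(x, torque, arm)

    batch = x.shape[:-1]
    # d torque / d theta (sho, elb):  A^T diag(m Fmax FV dFL) (-A / l0)
    wth = m * muscles.f_max * fv * dfl / muscles.l0
    dG_dth = -np.einsum("ij,...i,ik->...jk", A, wth, A)
    # d torque / d omega
    wom = m * muscles.f_max * fl * dfv / muscles.l0
    dG_dom = -np.einsum("ij,...i,ik->...jk", A, wom, A)
    # d torque / d m
    dG_dm = np.einsum("ij,...i->...ji", A, muscles.f_max * fl * fv)  # (..., 2, 6)

    _, om = _joint_view(x)
    oms, ome = om[..., 0], om[..., 1]
    # Coriolis derivatives
    dc_dthe = np.stack(
        [-hcoef * c2 * (2.0 * oms * ome + ome**2), hcoef * c2 * oms**2], axis=-1
    )
    dc_dom = np.empty(batch + (2, 2))
    dc_dom[..., 0, 0] = -hcoef * s2 * 2.0 * ome
    dc_dom[..., 0, 1] = -hcoef * s2 * (2.0 * oms + 2.0 * ome)
    dc_dom[..., 1, 0] = hcoef * s2 * 2.0 * oms
    dc_dom[..., 1, 1] = 0.0

    # d M / d theta_e applied to acc
    dM_acc = np.stack(
        [
            -2.0 * hcoef * s2 * acc[..., 0] - hcoef * s2 * acc[..., 1],
            -hcoef * s2 * acc[..., 0],
        ],
        axis=-1,
    )

    def minv_apply(v):
        vs = (m22 * v[..., 0] - m12 * v[..., 1]) / det
        ve = (m11 * v[..., 1] - m12 * v[..., 0]) / det
        return np.stack([vs, ve], axis=-1)

    # d acc / d theta (columns: sho, elb); Coriolis and M depend only on theta_e
    dtau_dth = dG_dth.copy()
    dtau_dth[..., :, 1] -= dc_dthe
    dtau_dth[..., :, 1] -= dM_acc  # term from d(M)/d theta_e acting on acc
    dacc_dth = np.stack(
        [minv_apply(dtau_dth[..., 0]), minv_apply(dtau_dth[..., 1])], axis=-1
    )
    dtau_dom = dG_dom - dc_dom - arm.viscosity * np.eye(2)
    dacc_dom = np.stack(
        [minv_apply(dtau_dom[..., 0]), minv_apply(dtau_dom[..., 1])], axis=-1
    )
    dacc_dm = np.stack([minv_apply(dG_dm[..., i]) for i in range(6)], axis=-1)

    dt = arm.dt
    Jx = np.zeros(batch + (4, 4))
    Jx[..., 0:2, 0:2] = np.eye(2)
    Jx[..., 0:2, 2:4] = dt * np.eye(2)
    Jx[..., 2:4, 0:2] = dt * dacc_dth
    Jx[..., 2:4, 2:4] = np.eye(2) + dt * dacc_dom
    Jm = np.zeros(batch + (4, 6))
    Jm[..., 2:4, :] = dt * dacc_dm
    # permute joint layout -> state layout on both state axes
    Jx = Jx[..., _PERM, :][..., :, _PERM]
    Jm = Jm[..., _PERM, :]
    return Jx, Jm


def hand_position(x: np.ndarray, arm: ArmParams) -> np.ndarray:
    """Forward kinematics: hand (x, y) in metres, shoulder at the origin."""
    x = np.asarray(x, dtype=float)
    ths = x[..., 1]
    the = x[..., 0]
    px = arm.l1 * np.cos(ths) + arm.l2 * np.cos(ths + the)
    py = arm.l1 * np.sin(ths) + arm.l2 * np.sin(ths + the)
    return np.stack([px, py], axis=-1)


def hand_velocity(x: np.ndarray, arm: ArmParams) -> np.ndarray:
    """Hand (vx, vy) in m/s from the joint state."""
    x = np.asarray(x, dtype=float)
    ths, the = x[..., 1], x[..., 0]
    oms, ome = x[..., 3], x[..., 2]
    s1, s12 = np.sin(ths), np.sin(ths + the)
    c1, c12 = np.cos(ths), np.cos(ths + the)
    vx = -arm.l1 * s1 * oms - arm.l2 * s12 * (oms + ome)
    vy = arm.l1 * c1 * oms + arm.l2 * c12 * (oms + ome)
    return np.stack([vx, vy], axis=-1)


def hand_jacobian(x: np.ndarray, arm: ArmParams) -> np.ndarray:
    """Jacobian of [px, py, vx, vy] w.r.t. the joint state (..., 4, 4), state layout."""
    x = np.asarray(x, dtype=float)
    ths, the = x[..., 1], x[..., 0]
    oms, ome = x[..., 3], x[..., 2]
    s1, s12 = np.sin(ths), np.sin(ths + the)
    c1, c12 = np.cos(ths), np.cos(ths + the)
    l1, l2 = arm.l1, arm.l2
    J = np.zeros(x.shape[:-1] + (4, 4))
    # position rows
    J[..., 0, 1] = -l1 * s1 - l2 * s12
    J[..., 0, 0] = -l2 * s12
    J[..., 1, 1] = l1 * c1 + l2 * c12
    J[..., 1, 0] = l2 * c12
    # velocity rows
    J[..., 2, 1] = -l1 * c1 * oms - l2 * c12 * (oms + ome)
    J[..., 2, 0] = -l2 * c12 * (oms + ome)
    J[..., 2, 3] = -l1 * s1 - l2 * s12
    J[..., 2, 2] = -l2 * s12
    J[..., 3, 1] = -l1 * s1 * oms - l2 * s12 * (oms + ome)
    J[..., 3, 0] = -l2 * s12 * (oms + ome)
    J[..., 3, 3] = l1 * c1 + l2 * c12
    J[..., 3, 2] = l2 * c12
    return J


def inverse_kinematics(hand_xy: np.ndarray, arm: ArmParams) -> np.ndarray:
    """Joint angles (shoulder, elbow) reaching the given hand position (elbow-up branch)."""
    p = np.asarray(hand_xy, dtype=float)
    r2 = p[..., 0] ** 2 + p[..., 1] ** 2
    cos_e = (r2 - arm.l1**2 - arm.l2**2) / (2.0 * arm.l1 * arm.l2)
    if np.any(np.abs(cos_e) > 1.0 + 1e-9):
        raise ValueError("target outside the arm workspace")
    the = np.arccos(np.clip(cos_e, -1.0, 1.0))
    ths = np.arctan2(p[..., 1], p[..., 0]) - np.arctan2(
        arm.l2 * np.sin(the), arm.l1 + arm.l2 * np.cos(the)
    )
    return np.stack([ths, the], axis=-1)
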