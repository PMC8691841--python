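"""Arm and muscle model: torque generation, integration, Jacobians, kinematics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from armdyn.plant import (
    ArmParams,
    MuscleParams,
    hand_jacobian,
    hand_position,
    inverse_kinematics,
    muscle_gains,
    muscle_torques,
    step_arm,
    step_arm_jacobians,
)

X0 = np.array([np.pi / 2, np.pi / 4, 0.0, 0.0])


def test_zero_activation_zero_torque(muscles):
    state = np.array([1.0, 0.3, -2.0, 4.0])
    assert np.allclose(muscle_torques(np.zeros(6), state, muscles), 0.0)


def test_single_muscle_at_optimum(muscles):
    # at the reference posture with zero velocity, FL = FV = 1 by construction
    for i in range(6):
        m = np.zeros(6)
        m[i] = 1.0
        torque = muscle_torques(m, X0, muscles)
        assert np.allclose(torque, muscles.f_max[i] * muscles.moment_arm[i])


def test_torque_matches_per_muscle_hand_computation(muscles):
    """Brute-force oracle: force = m * Fmax * FL * FV per muscle, summed over moment arms."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        m = rng.uniform(0, 1, 6)
        x = X0 + rng.normal(0, 0.4, 4)
        torque = muscle_torques(m, x, muscles)
        expected = np.zeros(2)
        th = np.array([x[1], x[0]])
        om = np.array([x[3], x[2]])
        for i in range(6):
            a = muscles.moment_arm[i]
            lnorm = 1.0 - a @ (th - muscles.ref_angles) / muscles.l0
            vnorm = -a @ om / muscles.l0
            fl = np.exp(-(((lnorm - 1) / muscles.fl_width) ** 2))
            if vnorm < 0:
                v = max(vnorm, -muscles.fv_vmax)
                fv = (1 + v / muscles.fv_vmax) / (
                    1 - v / (muscles.fv_vmax * muscles.fv_shorten_curv)
                )
            else:
                g = muscles.fv_lengthen_scale
                fv = muscles.fv_max_lengthen - (muscles.fv_max_lengthen - 1) * g / (g + vnorm)
            expected += m[i] * muscles.f_max[i] * fl * fv * a
        assert np.allclose(torque, expected, atol=1e-12)


def test_torque_linear_in_activation(muscles):
    rng = np.random.default_rng(3)
    m = rng.uniform(0, 1, 6)
    x = X0 + rng.normal(0, 0.2, 4)
    assert np.allclose(
        muscle_torques(2 * m, x, muscles), 2 * muscle_torques(m, x, muscles)
    )


def test_nonfinite_state_raises(muscles):
    with pytest.raises(FloatingPointError):
        muscle_torques(np.zeros(6), np.array([np.nan, 0, 0, 0]), muscles)


def test_rest_is_fixed_point(arm, muscles):
    """Horizontal plane, no gravity: any zero-velocity state with silent muscles stays put."""
    for angles in ([0.8, 0.4], [1.9, -0.2], [np.pi / 2, np.pi / 4]):
        x = np.array([angles[0], angles[1], 0.0, 0.0])
        assert np.allclose(step_arm(x, np.zeros(6), muscles, arm), x)


def test_single_euler_step_closed_form(arm, muscles):
    """From rest under constant load: acceleration = M^-1 torque, velocity = dt * acc."""
    load = np.array([0.3, 0.0])  # shoulder torque
    x1 = step_arm(X0, np.zeros(6), muscles, arm, load)
    the = X0[0]
    hcoef = arm.m2 * arm.l1 * arm.d2
    m11 = arm.i1 + arm.m1 * arm.d1**2 + arm.i2 + arm.m2 * (arm.l1**2 + arm.d2**2) \
        + 2 * hcoef * np.cos(the)
    m12 = arm.i2 + arm.m2 * arm.d2**2 + hcoef * np.cos(the)
    m22 = arm.i2 + arm.m2 * arm.d2**2
    Minv = np.linalg.inv(np.array([[m11, m12], [m12, m22]]))
    acc = Minv @ load  # (sho, elb)
    assert np.allclose(x1[:2], X0[:2])  # angles unchanged (velocities were zero)
    assert np.allclose(x1[2:], [arm.dt * acc[1], arm.dt * acc[0]])


def test_euler_matches_fine_reference_integrator(arm, muscles):
    """1 s under constant torque agrees with an adaptive ODE solver within 1% in angle."""
    load = np.array([0.05, -0.03])

    def deriv(t, x):
        xn = step_arm(x, np.zeros(6), muscles, arm, load)
        return (xn - x) / arm.dt  # Euler step encodes the vector field exactly

    ref = solve_ivp(deriv, (0, 1.0), X0, rtol=1e-10, atol=1e-12)
    x = X0.copy()
    for _ in range(100):
        x = step_arm(x, np.zeros(6), muscles, arm, load)
    excursion = np.abs(ref.y[:2, -1] - X0[:2]).max()
    assert np.abs(x[:2] - ref.y[:2, -1]).max() < 0.01 * max(excursion, 1.0)


def test_step_jacobians_match_finite_differences(arm, muscles):
    rng = np.random.default_rng(0)
    for _ in range(5):
        x = X0 + rng.normal(0, 0.3, 4)
        m = rng.uniform(0, 0.5, 6)
        load = rng.normal(0, 0.1, 2)
        Jx, Jm = step_arm_jacobians(x, m, muscles, arm, load)
        eps = 1e-6
        for i in range(4):
            e = np.zeros(4)
            e[i] = eps
            col = (step_arm(x + e, m, muscles, arm, load) - step_arm(x - e, m, muscles, arm, load)) / (2 * eps)
            assert np.allclose(Jx[:, i], col, atol=1e-7)
        for i in range(6):
            e = np.zeros(6)
            e[i] = eps
            col = (step_arm(x, m + e, muscles, arm, load) - step_arm(x, m - e, muscles, arm, load)) / (2 * eps)
            assert np.allclose(Jm[:, i], col, atol=1e-7)


def test_hand_jacobian_matches_finite_differences(arm):
    from armdyn.plant import hand_velocity

    rng = np.random.default_rng(1)
    x = X0 + rng.normal(0, 0.3, 4)
    J = hand_jacobian(x, arm)
    eps = 1e-6
    for i in range(4):
        e = np.zeros(4)
        e[i] = eps
        pv_p = np.concatenate([hand_position(x + e, arm), hand_velocity(x + e, arm)])
        pv_m = np.concatenate([hand_position(x - e, arm), hand_velocity(x - e, arm)])
        assert np.allclose(J[:, i], (pv_p - pv_m) / (2 * eps), atol=1e-6)


def test_forward_kinematics_geometry(arm):
    # fully extended arm along +x when both angles are zero
    assert np.allclose(hand_position(np.zeros(4), arm), [arm.l1 + arm.l2, 0.0])
    # elbow at 90 degrees, shoulder at 0
    x = np.array([np.pi / 2, 0.0, 0.0, 0.0])
    assert np.allclose(hand_position(x, arm), [arm.l1, arm.l2])


def test_inverse_kinematics_round_trip(arm):
    rng = np.random.default_rng(5)
    for _ in range(20):
        th = np.array([rng.uniform(-1, 2), rng.uniform(0.2, 2.5)])
        x = np.array([th[1], th[0], 0.0, 0.0])
        target = hand_position(x, arm)
        rec = inverse_kinematics(target, arm)
        assert np.allclose(rec, th, atol=1e-9)


def test_gains_at_optimum_and_saturation(muscles):
    fl, fv, _, _ = muscle_gains(X0, muscles)
    assert np.allclose(fl, 1.0) and np.allclose(fv, 1.0)
    # fast lengthening saturates below the cap; fast shortening approaches zero force
    fast = np.array([X0[0], X0[1], 50.0, 50.0])
    fl2, fv2, _, _ = muscle_gains(fast, muscles)
    assert np.all(fv2 <= muscles.fv_max_lengthen + 1e-12)
    assert np.all(fv2 >= 0.0)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ArmParams(m1=-1.0)
    with pytest.raises(ValueError):
        ArmParams(dt=0.02)
    with pytest.raises(ValueError):
        MuscleParams(moment_arm=np.ones((6, 2)))  # all biarticular
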