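"""Two-layer leaky recurrent controller with delayed sensory feedback.

The controller maps task-goal inputs plus delayed limb feedback (joint
kinematics and muscle activations, lagged by a physiological 50 ms) to the
activations of six muscles.  Both layers are leaky tanh units::

    h[t+1] = (1 - l_n) h[t] + l_n tanh(W_sh I[t] + W_hh h[t] + b_h)
    o[t+1] = (1 - l_n) o[t] + l_n tanh(W_ho h[t] + W_oo o[t] + b_o)
    m[t+1] = (1 - l_m) m[t] + l_m relu(W_ou o[t])

with leak fractions l_n = dt / tau_n and l_m = dt / tau_m.  The NO-REC
variant removes the recurrent matrices *and* the leak terms, making each
layer a memoryless function of its input: h[t+1] = tanh(W_sh I[t] + b_h),
o[t+1] = tanh(W_ho h[t] + b_o).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass
class NetworkParams:
    """Architecture and timing of the controller.

    n_units: units per layer (500 in the full-scale model; analyses here also
      support a reduced desk scale).
    tau_n / tau_m: unit and muscle time constants (s); with dt = 10 ms the
      leak fractions are l_n = 0.5 and l_m = 0.2.
    delay: sensory feedback delay (s); must be a multiple of dt.
    recurrent: REC (True) vs NO-REC (False) variant.
    init: "uniform" U(-1/sqrt(N_inp), 1/sqrt(N_inp)) — the standard
      fan-in-scaled scheme — or "gaussian" N(0, (g/sqrt(N_inp))^2), the
      strong-recurrence initialization used by autonomous RNN models.
    literal_n_scaling: scale both schemes by 1/N_inp instead of
      1/sqrt(N_inp) (vanishingly weak coupling at large N; kept for
      comparison).
    """

    n_units: int = 500
    tau_n: float = 0.020
    tau_m: float = 0.050
    dt: float = 0.010
    delay: float = 0.050
    recurrent: bool = True
    init: str = "uniform"
    gain: float = 1.5
    literal_n_scaling: bool = False

    @property
    def l_n(self) -> float:
        return self.dt / self.tau_n

    @property
    def l_m(self) -> float:
        return self.dt / self.tau_m

    @property
    def delay_steps(self) -> int:
        steps = self.delay / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("feedback delay must be a multiple of dt")
        return int(round(steps))


@dataclass
class Weights:
    """Connection weights and biases of the two-layer controller."""

    w_sh: np.ndarray  # (N, n_inputs)
    w_hh: np.ndarray  # (N, N)
    w_ho: np.ndarray  # (N, N)
    w_oo: np.ndarray  # (N, N)
    w_ou: np.ndarray  # (6, N)
    b_h: np.ndarray  # (N,)
    b_o: np.ndarray  # (N,)

    def copy(self) -> "Weights":
        return Weights(*(getattr(self, f).copy() for f in _FIELDS))

    def as_list(self) -> list[np.ndarray]:
        return [getattr(self, f) for f in _FIELDS]


_FIELDS = ("w_sh", "w_hh", "w_ho", "w_oo", "w_ou", "b_h", "b_o")


def init_weights(params: NetworkParams, n_inputs: int, rng: np.random.Generator) -> Weights:
    """Draw initial weights; biases start at zero.

    Uniform scheme: each entry ~ U(-1/sqrt(N_inp), 1/sqrt(N_inp)) where
    N_inp is the fan-in (row length) of its matrix.  Gaussian scheme:
    entries ~ N(0, (g / sqrt(N_inp))^2) with g > 1, encouraging strong
    intrinsic dynamics.
    """
    n = params.n_units

    def draw(shape: tuple[int, int]) -> np.ndarray:
        fan_in = shape[1]
        scale = 1.0 / fan_in if params.literal_n_scaling else 1.0 / np.sqrt(fan_in)
        if params.init == "uniform":
            return rng.uniform(-scale, scale, size=shape)
        if params.init == "gaussian":
            return rng.normal(0.0, params.gain * scale, size=shape)
        raise ValueError(f"unknown init scheme {params.init!r}")

    w = Weights(
        w_sh=draw((n, n_inputs)),
        w_hh=draw((n, n)),
        w_ho=draw((n, n)),
        w_oo=draw((n, n)),
        w_ou=draw((6, n)),
        b_h=np.zeros(n),
        b_o=np.zeros(n),
    )
    if not params.recurrent:
        w.w_hh[:] = 0.0
        w.w_oo[:] = 0.0
    return w


@dataclass
class ControllerState:
    """Instantaneous state of the controller plus its feedback delay lines."""

    h: np.ndarray
    o: np.ndarray
    m: np.ndarray
    x_buffer: "DelayLine"
    m_buffer: "DelayLine"


class DelayLine:
    """Fixed-lag ring buffer implementing the sensory transmission delay.

    ``step(x_t)`` records the current sample and returns the sample from
    ``lag`` steps ago (identity when lag = 0).  The buffer is pre-filled with
    the trial's initial state, so feedback before t = delay reflects the
    starting posture rather than a spurious zero transient.
    """

    def __init__(self, lag_steps: int, initial: np.ndarray):
        if lag_steps < 0:
            raise ValueError("lag must be nonnegative")
        self.lag = lag_steps
        self._buf = [np.array(initial, dtype=float, copy=True) for _ in range(lag_steps)]
        self._head = 0

    def step(self, value: np.ndarray) -> np.ndarray:
        value = np.asarray(value, dtype=float)
        if self.lag == 0:
            return value
        out = self._buf[self._head]
        self._buf[self._head] = value.copy()
        self._head = (self._head + 1) % self.lag
        return out

    def peek(self) -> np.ndarray:
        """The sample that the next ``step`` call will return (no mutation)."""
        if self.lag == 0:
            raise ValueError("peek is undefined for a zero-lag line; feedback is instantaneous")
        return self._buf[self._head]


def init_state(
    params: NetworkParams, x0: np.ndarray, batch_shape: tuple[int, ...] = ()
) -> ControllerState:
    """Zero network/muscle activity; delay lines pre-filled with the initial plant state."""
    n = params.n_units
    h = np.zeros(batch_shape + (n,))
    o = np.zeros(batch_shape + (n,))
    m = np.zeros(batch_shape + (6,))
    lag = params.delay_steps
    return ControllerState(
        h=h,
        o=o,
        m=m,
        x_buffer=DelayLine(lag, np.broadcast_to(x0, batch_shape + (np.shape(x0)[-1],))),
        m_buffer=DelayLine(lag, m),
    )


def delayed_feedback(
    state: ControllerState, x_now: np.ndarray, m_now: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Push the current plant state/muscle vector and return the lagged feedback pair."""
    return state.x_buffer.step(x_now), state.m_buffer.step(m_now)


def step_network(
    state: ControllerState,
    inputs: np.ndarray,
    params: NetworkParams,
    weights: Weights,
) -> ControllerState:
    """Advance layer activities one step given the concatenated input vector."""
    inputs = np.asarray(inputs, dtype=float)
    if inputs.shape[-1] != weights.w_sh.shape[1]:
        raise ValueError(
            f"input dimension {inputs.shape[-1]} does not match W_sh fan-in {weights.w_sh.shape[1]}"
        )
    ln = params.l_n
    if params.recurrent:
        h_new = (1 - ln) * state.h + ln * np.tanh(
            inputs @ weights.w_sh.T + state.h @ weights.w_hh.T + weights.b_h
        )
        o_new = (1 - ln) * state.o + ln * np.tanh(
            state.h @ weights.w_ho.T + state.o @ weights.w_oo.T + weights.b_o
        )
    else:
        h_new = np.tanh(inputs @ weights.w_sh.T + weights.b_h)
        o_new = np.tanh(state.h @ weights.w_ho.T + weights.b_o)
    return replace(state, h=h_new, o=o_new)


def step_muscle(
    m: np.ndarray, o: np.ndarray, params: NetworkParams, weights: Weights
) -> np.ndarray:
    """Leaky first-order muscle activation driven by the rectified output-layer readout."""
    drive = np.maximum(o @ weights.w_ou.T, 0.0)
    return (1 - params.l_m) * np.asarray(m, dtype=float) + params.l_m * drive


def smoothed_go_cue(t_steps: int, go_step: int, dt: float = 0.010, sd: float = 0.020) -> np.ndarray:
    """GO-cue channel: high (1) = hold, low (0) = move, step smoothed by a 20 ms SD Gaussian."""
    from scipy.ndimage import gaussian_filter1d

    cue = np.zeros(t_steps)
    cue[:go_step] = 1.0
    return gaussian_filter1d(cue, sd / dt, mode="nearest")
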