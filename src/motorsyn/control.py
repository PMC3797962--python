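"""Linear feedback control and first-order muscle activation dynamics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError


@dataclass
class ControllerGains:
    """Diagonal PD gains: u = k_pos*(y* - y) + k_vel*(ydot* - ydot)."""

    k_pos: np.ndarray
    k_vel: np.ndarray

    def __post_init__(self):
        self.k_pos = np.atleast_1d(np.asarray(self.k_pos, dtype=float))
        self.k_vel = np.atleast_1d(np.asarray(self.k_vel, dtype=float))
        if self.k_pos.shape != self.k_vel.shape:
            raise InvalidParameterError("k_pos and k_vel must have equal length")
        if np.any(self.k_pos < 0) or np.any(self.k_vel < 0):
            raise InvalidParameterError("gains must be non-negative")


def feedback_control(y_des, ydot_des, y, ydot, gains: ControllerGains) -> np.ndarray:
    """Elementwise PD law tracking the desired trajectory."""
    y_des, ydot_des, y, ydot = (np.atleast_1d(np.asarray(a, float)) for a in (y_des, ydot_des, y, ydot))
    if not (y_des.shape == ydot_des.shape == y.shape == ydot.shape == gains.k_pos.shape):
        raise InvalidParameterError("feedback_control: length mismatch")
    return gains.k_pos * (y_des - y) + gains.k_vel * (ydot_des - ydot)


@dataclass
class ActivationState:
    """Per-muscle activation in [0, 1] with rise/fall time constants (s).

    Muscles cannot produce force instantaneously; the excitation-to-
    activation lag is the first-order law

        a_dot = (e^2 - e a) / tau_rise + (e - a) / tau_fall,

    which rises with the faster constant and decays with the slower one.
    Defaults tau_rise = 10 ms, tau_fall = 40 ms.
    """

    a: np.ndarray
    tau_rise: float = 0.010
    tau_fall: float = 0.040

    def __post_init__(self):
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        if not (self.tau_rise > 0 and self.tau_fall > 0):
            raise InvalidParameterError("activation time constants must be positive")


def step_activation(state: ActivationState, excitation, dt: float) -> ActivationState:
    """Explicit-Euler step of the activation law; result clamped to [0, 1].

    The excitation is expected to be clipped to [0, 1] upstream (synergy
    outputs can be negative; the plant clips them before this call).
    """
    if not dt > 0:
        raise InvalidParameterError("dt must be positive")
    e = np.broadcast_to(np.asarray(excitation, dtype=float), state.a.shape)
    a = state.a
    adot = (e**2 - e * a) / state.tau_rise + (e - a) / state.tau_fall
    a_new = np.clip(a + dt * adot, 0.0, 1.0)
    return ActivationState(a_new, tau_rise=state.tau_rise, tau_fall=state.tau_fall)
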