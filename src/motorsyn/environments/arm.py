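"""Muscle-actuated planar arm for multi-directional reaching.

A deliberately simple stand-in plant: a planar two-link arm (shoulder and
elbow hinges, sagittal plane) driven by six lumped muscles — mono-articular
flexor/extensor pairs at each joint plus one bi-articular pair — with
constant moment arms and force equal to activation times maximum isometric
force.  Muscle excitations pass through first-order activation dynamics.
Control is open loop: the learnable synergy superposition is the excitation
pattern itself.

The plant captures the structure of muscle-space control (redundancy,
antagonism, activation lag) without tendon dynamics or wrapping geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..control import ActivationState, step_activation
from ..errors import InvalidParameterError
from ..primitives import BasisKind, PhaseState, PrimitiveConfig, initial_phase, step_phase
from . import EpisodeResult

_DEF_MOMENT_ARMS = np.array(
    [
        # (shoulder, elbow) moment arms in m; flexors positive
        [0.04, 0.0],    # shoulder flexor
        [-0.04, 0.0],   # shoulder extensor
        [0.0, 0.025],   # elbow flexor
        [0.0, -0.025],  # elbow extensor
        [0.03, 0.025],  # bi-articular flexor
        [-0.03, -0.025],  # bi-articular extensor
    ]
)
_DEF_F_MAX = np.array([600.0, 600.0, 400.0, 400.0, 300.0, 300.0])


@dataclass
class ArmTask:
    """Six reaching targets on a circle around the initial marker position.

    The marker sits at the wrist (distal end of the forearm).  Angles are
    measured from the downward vertical; ``q0`` is the initial posture.
    """

    n_targets: int = 6
    radius: float = 0.15
    n_steps: int = 500
    dt: float = 0.001
    l1: float = 0.30
    l2: float = 0.33
    m1: float = 1.9
    m2: float = 1.5
    gravity: float = 9.81
    q0: tuple = (0.9, 1.4)
    moment_arms: np.ndarray = field(default_factory=lambda: _DEF_MOMENT_ARMS.copy())
    f_max: np.ndarray = field(default_factory=lambda: _DEF_F_MAX.copy())
    tau_rise: float = 0.010
    tau_fall: float = 0.040

    def __post_init__(self):
        self.moment_arms = np.asarray(self.moment_arms, dtype=float)
        self.f_max = np.asarray(self.f_max, dtype=float)
        if self.moment_arms.shape != (self.n_muscles, 2):
            raise InvalidParameterError("moment-arm matrix must be (n_muscles, 2)")
        if not self.radius > 0:
            raise InvalidParameterError("target radius must be positive")

    @property
    def n_muscles(self) -> int:
        return len(self.f_max)

    @property
    def n_tasks(self) -> int:
        return self.n_targets

    def forward_kinematics(self, q: np.ndarray) -> np.ndarray:
        """Marker (wrist) position for joint angles q = (shoulder, elbow)."""
        q1, q2 = q
        elbow = np.array([self.l1 * np.sin(q1), -self.l1 * np.cos(q1)])
        return elbow + np.array(
            [self.l2 * np.sin(q1 + q2), -self.l2 * np.cos(q1 + q2)]
        )

    def targets(self) -> np.ndarray:
        """(K, 2) target positions, equally spaced on the reach circle."""
        start = self.forward_kinematics(np.asarray(self.q0, dtype=float))
        ang = 2.0 * np.pi * np.arange(self.n_targets) / self.n_targets
        return start + self.radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)


def _arm_dynamics(task: ArmTask, q, qd, tau):
    """Standard two-link equations of motion (point masses + rod inertia)."""
    l1, l2, m1, m2 = task.l1, task.l2, task.m1, task.m2
    c1, c2 = 0.5 * l1, 0.5 * l2
    i1, i2 = m1 * l1**2 / 12.0, m2 * l2**2 / 12.0
    cq2, sq2 = np.cos(q[1]), np.sin(q[1])
    m11 = i1 + i2 + m1 * c1**2 + m2 * (l1**2 + c2**2 + 2 * l1 * c2 * cq2)
    m12 = i2 + m2 * (c2**2 + l1 * c2 * cq2)
    m22 = i2 + m2 * c2**2
    M = np.array([[m11, m12], [m12, m22]])
    h = m2 * l1 * c2 * sq2
    cor = np.array(
        [-h * qd[1] * (2 * qd[0] + qd[1]), h * qd[0] ** 2]
    )
    g = task.gravity
    grav = np.array(
        [
            (m1 * c1 + m2 * l1) * g * np.sin(q[0]) + m2 * c2 * g * np.sin(q[0] + q[1]),
            m2 * c2 * g * np.sin(q[0] + q[1]),
        ]
    )
    return np.linalg.solve(M, tau - cor - grav)


def arm_rollout(
    task: ArmTask,
    excitation,
    k: int = 0,
    seed: int | np.random.Generator | None = 0,
    cfg: PrimitiveConfig | None = None,
    gravity_compensation: bool = False,
) -> EpisodeResult:
    """Open-loop reaching episode.

    ``excitation`` is a callable ``(phase_value, k) -> per-muscle array``;
    its output is clipped to [0, 1], lagged by the activation dynamics and
    converted to joint torques through the constant moment-arm matrix.  With
    ``gravity_compensation`` the static gravity torque at the current
    posture is cancelled (used by diagnostics; learning runs leave it off).
    Deterministic given the seed (the default plant is noise-free; the seed
    argument keeps the rollout interface uniform across environments).
    """
    D = task.n_muscles
    if cfg is None:
        cfg = PrimitiveConfig(
            kind=BasisKind.DISCRETE,
            tau=task.n_steps * task.dt,
            dt=task.dt,
            n_steps=task.n_steps,
            goal=np.zeros(D),
        )
    T = task.n_steps
    q = np.asarray(task.q0, dtype=float).copy()
    qd = np.zeros(2)
    act = ActivationState(np.zeros(D), tau_rise=task.tau_rise, tau_fall=task.tau_fall)
    phase = initial_phase(cfg)

    y = np.empty((T, 2))
    ydot = np.empty((T, 2))
    exc_trace = np.empty((T, D))
    act_trace = np.empty((T, D))
    marker = np.empty((T, 2))
    ph = np.empty(T)

    for t in range(T):
        y[t] = q
        ydot[t] = qd
        ph[t] = phase.value
        marker[t] = task.forward_kinematics(q)

        e = np.zeros(D) if excitation is None else np.asarray(excitation(phase.value, k), dtype=float)
        if e.shape != (D,):
            raise InvalidParameterError(
                f"excitation dimension {e.shape} does not match muscle count {D}"
            )
        e = np.clip(e, 0.0, 1.0)
        exc_trace[t] = e
        act = step_activation(act, e, task.dt)
        act_trace[t] = act.a

        forces = act.a * task.f_max
        tau = task.moment_arms.T @ forces
        if gravity_compensation:
            tau = tau + _gravity_torque(task, q)
        qdd = _arm_dynamics(task, q, qd, tau)
        qd = qd + task.dt * qdd
        q = q + task.dt * qd
        phase = step_phase(phase, cfg)

    return EpisodeResult(
        y=y,
        ydot=ydot,
        excitations=exc_trace,
        phase=ph,
        extras={"marker": marker, "activations": act_trace},
    )


def _gravity_torque(task: ArmTask, q):
    l1, m1, m2 = task.l1, task.m1, task.m2
    c1, c2 = 0.5 * task.l1, 0.5 * task.l2
    g = task.gravity
    return np.array(
        [
            (m1 * c1 + m2 * l1) * g * np.sin(q[0]) + m2 * c2 * g * np.sin(q[0] + q[1]),
            m2 * c2 * g * np.sin(q[0] + q[1]),
        ]
    )


def reaching_task_terms(result: EpisodeResult, task: ArmTask, k: int) -> tuple[float, float]:
    """(tracking, excitation-penalty) terms for one target.

    Tracking: 3 times the time-averaged Euclidean marker-to-target distance.
    Penalty: 1e-3 times the integral of the squared excitation vector over
    the phase interval, approximated by the trapezoid rule on the recorded
    phase trace.
    """
    if "marker" not in result.extras or result.excitations is None or result.phase is None:
        raise InvalidParameterError("episode lacks marker/excitation/phase records")
    target = task.targets()[k]
    dist = np.linalg.norm(target - result.extras["marker"], axis=1)
    track = 3.0 * float(dist.mean())
    sq = np.sum(result.excitations**2, axis=1)
    # phase decreases over the episode; integrate on the increasing grid
    penalty = 1e-3 * float(abs(np.trapezoid(sq, result.phase)))
    return track, penalty


def reaching_task_cost(result: EpisodeResult, task: ArmTask, k: int) -> float:
    return float(sum(reaching_task_terms(result, task, k)))


def reaching_cost_terms(results: list[EpisodeResult], task: ArmTask) -> list[tuple[float, float]]:
    """Per-task (tracking, excitation-penalty) pairs for all K targets."""
    if len(results) != task.n_targets:
        raise InvalidParameterError(
            f"expected {task.n_targets} episodes, got {len(results)}"
        )
    return [reaching_task_terms(res, task, k) for k, res in enumerate(results)]


def reaching_cost(results: list[EpisodeResult], task: ArmTask) -> float:
    """Total multi-task reaching objective (sum over the K targets)."""
    return float(sum(a + b for a, b in reaching_cost_terms(results, task)))
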