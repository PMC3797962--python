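"""Point-mass via-point task.

A unit point mass is accelerated by a PD controller tracking the primitive's
desired trajectory, with additive Gaussian motor noise on the control.  Each
of the K tasks must pass through its via-point at a given time index and end
at the goal at rest, with a small control penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..control import ControllerGains, feedback_control
from ..errors import InvalidParameterError
from ..primitives import PrimitiveTrajectory
from . import EpisodeResult


@dataclass
class PointMassTask:
    """Via-point task set: K via-points, common goal, horizon and noise.

    ``t_vp`` is the 0-based step index at which the via-point is evaluated
    (default: mid-horizon).  ``control_penalty`` selects the energy term:
    "squared" (sum of u^2, default) or "as_printed" (plain sum of u).
    """

    via_points: tuple = (0.2, 0.1, 0.0, -0.1, -0.2)
    t_vp: int | None = None
    goal: float = 1.0
    n_steps: int = 50
    dt: float = 0.01
    mass: float = 1.0
    sigma: float = 0.5
    gains: ControllerGains = field(default_factory=lambda: ControllerGains(400.0, 15.0))
    control_penalty: str = "squared"

    def __post_init__(self):
        if self.t_vp is None:
            self.t_vp = self.n_steps // 2
        if not 1 <= self.t_vp <= self.n_steps - 1:
            raise InvalidParameterError("t_vp must lie inside the horizon")
        if not self.mass > 0:
            raise InvalidParameterError("mass must be positive")
        if self.control_penalty not in ("squared", "as_printed"):
            raise InvalidParameterError("control_penalty must be 'squared' or 'as_printed'")

    @property
    def n_tasks(self) -> int:
        return len(self.via_points)


def pointmass_rollout(
    task: PointMassTask,
    desired: PrimitiveTrajectory,
    seed: int | np.random.Generator | None = 0,
) -> EpisodeResult:
    """Closed-loop episode: y_ddot = (u + noise) / mass, u from the PD law.

    The recorded control is the commanded (noise-free) u; the motor noise
    perturbs the plant.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = task.n_steps
    y = np.empty(T)
    v = np.empty(T)
    u = np.empty(T - 1)
    y[0] = desired.y[0, 0]
    v[0] = desired.ydot[0, 0]
    noise = rng.normal(0.0, task.sigma, size=T - 1) if task.sigma > 0 else np.zeros(T - 1)
    for t in range(T - 1):
        u[t] = feedback_control(
            desired.y[t], desired.ydot[t], y[t], v[t], task.gains
        )[0]
        acc = (u[t] + noise[t]) / task.mass
        v[t + 1] = v[t] + task.dt * acc
        y[t + 1] = y[t] + task.dt * v[t]
    return EpisodeResult(y=y, ydot=v, u=u, phase=desired.phase.copy())


def viapoint_cost_terms(result: EpisodeResult, task: PointMassTask, k: int) -> tuple[float, float, float]:
    """(via-point, terminal, control-penalty) terms of the task cost."""
    if result.u is None:
        raise InvalidParameterError("episode carries no controls")
    y, v, u = result.y, result.ydot, result.u
    if len(y) <= task.t_vp:
        raise InvalidParameterError("trajectory does not cover the via time")
    vp = task.via_points[k]
    term_vp = 1e5 * (y[task.t_vp] - vp) ** 2
    term_goal = 1e4 * (v[-1] ** 2 + 10.0 * (y[-1] - task.goal) ** 2)
    if task.control_penalty == "squared":
        term_u = 5e-4 * float(np.sum(u**2))
    else:
        term_u = 5e-4 * float(np.sum(u))
    return float(term_vp), float(term_goal), term_u


def viapoint_cost(result: EpisodeResult, task: PointMassTask, k: int) -> float:
    """Scalar task cost: via-point + terminal + control-penalty terms."""
    return float(sum(viapoint_cost_terms(result, task, k)))
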