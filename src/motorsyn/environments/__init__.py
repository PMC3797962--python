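"""Benchmark plants and their cost functions."""

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EpisodeResult:
    """One simulated episode: trajectory, controls and auxiliary records.

    ``y``/``ydot`` are the simulated states (T, D) or (T,), ``u`` the applied
    controls (T-1, D), ``excitations`` the muscle excitations where relevant,
    ``phase`` the phase trace and ``extras`` environment-specific records
    (step heights, marker path, impact flags, ...).  ``cost`` is filled by
    the task's cost function.
    """

    y: np.ndarray
    ydot: np.ndarray
    u: np.ndarray | None = None
    excitations: np.ndarray | None = None
    phase: np.ndarray | None = None
    cost: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return len(self.y)


from .pointmass import PointMassTask, pointmass_rollout, viapoint_cost, viapoint_cost_terms  # noqa: E402,F401
from .walker import WalkerParams, WalkerState, WalkerTask, walker_cost, walker_rollout, walker_step  # noqa: E402,F401
from .arm import ArmTask, arm_rollout, reaching_cost, reaching_cost_terms, reaching_task_cost  # noqa: E402,F401
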