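"""Phase dynamics, forcing functions and the stable attractor system.

Each actuator follows a damped-spring attractor toward its goal,

    tau * z_dot = alpha_z * (beta_z * (g - y) - z) + f,
    tau * y_dot = z,

modulated by a learnable forcing ``f`` of a phase variable.  Discrete
movements use an exponentially decaying phase ``tau * s_dot = -alpha_s * s``;
rhythmic movements use a linearly advancing cyclic phase ``tau * phi_dot = 1``.
The forcing is either a normalized mixture of fixed-grid kernels (the classic
single-task primitive) or a superposition of shared synergies scaled by
task-specific weights beta and time shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .basis import BasisKind, SynergyShape, eval_synergy, eval_synergy_all_dims
from .errors import DegenerateNormalizerError, InvalidParameterError, SchemeMismatchError


@dataclass
class PrimitiveConfig:
    """Attractor and phase constants for one movement.

    alpha_s defaults to ``tau * ln(100) / (T * dt)`` so the discrete phase
    has decayed to about 0.01 at the end of the horizon.
    """

    alpha_z: float = 2.0
    beta_z: float = 0.9
    tau: float = 0.1
    goal: np.ndarray = 1.0
    dt: float = 0.01
    n_steps: int = 50
    kind: BasisKind = BasisKind.DISCRETE
    alpha_s: float | None = None

    def __post_init__(self):
        self.kind = BasisKind(self.kind)
        self.goal = np.atleast_1d(np.asarray(self.goal, dtype=float))
        for name in ("alpha_z", "beta_z", "tau", "dt"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.n_steps < 1:
            raise InvalidParameterError("n_steps must be >= 1")
        if self.alpha_s is None:
            self.alpha_s = self.tau * np.log(100.0) / (self.n_steps * self.dt)
        if not self.alpha_s > 0:
            raise InvalidParameterError("alpha_s must be positive")

    @property
    def n_dims(self) -> int:
        return self.goal.size


@dataclass
class PhaseState:
    """Phase value: s in (0, 1] for discrete, phi in R for rhythmic."""

    value: float = 1.0


def step_phase(state: PhaseState, cfg: PrimitiveConfig) -> PhaseState:
    """One explicit-Euler phase update at the configured dt."""
    if cfg.kind is BasisKind.DISCRETE:
        s = state.value + cfg.dt * (-cfg.alpha_s * state.value / cfg.tau)
        return PhaseState(s)
    return PhaseState(state.value + cfg.dt / cfg.tau)


def initial_phase(cfg: PrimitiveConfig) -> PhaseState:
    return PhaseState(1.0 if cfg.kind is BasisKind.DISCRETE else 0.0)


@dataclass
class AttractorState:
    """Per-DoF desired position ``y`` and internal variable ``z``.

    The desired velocity is ``z / tau`` by construction, so it is derived
    rather than integrated separately.
    """

    y: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        self.z = np.atleast_1d(np.asarray(self.z, dtype=float))

    def ydot(self, tau: float) -> np.ndarray:
        return self.z / tau


def step_attractor(state: AttractorState, f, cfg: PrimitiveConfig) -> AttractorState:
    """Explicit-Euler update of the damped-spring attractor under forcing f."""
    f = np.broadcast_to(np.asarray(f, dtype=float), state.y.shape)
    zdot = (cfg.alpha_z * (cfg.beta_z * (cfg.goal - state.y) - state.z) + f) / cfg.tau
    ydot = state.z / cfg.tau
    return AttractorState(state.y + cfg.dt * ydot, state.z + cfg.dt * zdot)


class CoefficientScheme(str, Enum):
    """How task-specific weights and shifts attach to the shared synergies.

    per_dimension:  beta and shifts indexed (m, k, d) — the Hadamard form.
    time_varying:   scalar beta and a single shift per (m, k), shared by all
                    dimensions — a time-varying synergy shifted as a whole.
    dmp_special_case: single synergy with unit weight and zero shift,
                    reproducing the classic primitive forcing.
    """

    PER_DIMENSION = "per_dimension"
    TIME_VARYING = "time_varying"
    DMP_SPECIAL_CASE = "dmp_special_case"


@dataclass
class TaskCoefficients:
    """Task-specific mixing weights ``beta`` and time shifts ``dshift``.

    Shapes: ``(M, K, D)`` for the per-dimension scheme, ``(M, K)`` for the
    time-varying and special-case schemes.  When ``learn_shifts`` is False
    all shifts must be identically zero.
    """

    scheme: CoefficientScheme
    beta: np.ndarray
    dshift: np.ndarray | None = None
    learn_shifts: bool = False

    def __post_init__(self):
        self.scheme = CoefficientScheme(self.scheme)
        self.beta = np.asarray(self.beta, dtype=float)
        expected_ndim = 3 if self.scheme is CoefficientScheme.PER_DIMENSION else 2
        if self.beta.ndim != expected_ndim:
            raise SchemeMismatchError(
                f"beta must have {expected_ndim} axes for scheme {self.scheme.value}, "
                f"got shape {self.beta.shape}"
            )
        if self.dshift is None:
            self.dshift = np.zeros_like(self.beta)
        else:
            self.dshift = np.asarray(self.dshift, dtype=float)
        if self.dshift.shape != self.beta.shape:
            raise SchemeMismatchError("dshift shape must match beta shape")
        if not self.learn_shifts and np.any(self.dshift != 0.0):
            raise SchemeMismatchError("dshift must be zero when learn_shifts is False")

    @property
    def n_synergies(self) -> int:
        return self.beta.shape[0]

    @property
    def n_tasks(self) -> int:
        return self.beta.shape[1]


@dataclass
class DMPWeights:
    """Classic primitive parametrization: learnable weights on a fixed kernel
    grid shared by all dimensions."""

    kind: BasisKind
    w: np.ndarray          # (D, N)
    means: np.ndarray      # (N,)
    bandwidths: np.ndarray  # (N,)

    def __post_init__(self):
        self.kind = BasisKind(self.kind)
        self.w = np.atleast_2d(np.asarray(self.w, dtype=float))
        self.means = np.asarray(self.means, dtype=float)
        self.bandwidths = np.asarray(self.bandwidths, dtype=float)
        if self.w.shape[1] != self.means.size or self.means.size != self.bandwidths.size:
            raise InvalidParameterError("weight/grid sizes inconsistent")
        if np.any(self.bandwidths <= 0):
            raise InvalidParameterError("grid bandwidths must be positive")


def dmp_grid(kind: BasisKind, n_basis: int) -> tuple[np.ndarray, np.ndarray]:
    """Equally spaced kernel means with ~50% neighbor overlap.

    Discrete: means on [0, 1], width such that adjacent kernels meet at value
    0.5 halfway between centers.  Rhythmic: means on [0, 2*pi), concentration
    chosen the same way.
    """
    kind = BasisKind(kind)
    if n_basis < 1:
        raise InvalidParameterError("need at least one kernel")
    if kind is BasisKind.DISCRETE:
        means = np.linspace(0.0, 1.0, n_basis)
        spacing = 1.0 / max(n_basis - 1, 1)
        h = spacing / (2.0 * np.sqrt(2.0 * np.log(2.0))) if n_basis > 1 else 0.5
        return means, np.full(n_basis, h)
    means = np.linspace(0.0, 2.0 * np.pi, n_basis, endpoint=False)
    if n_basis > 1:
        spacing = 2.0 * np.pi / n_basis
        h = np.log(2.0) / (1.0 - np.cos(spacing / 2.0))
    else:
        h = 1.0
    return means, np.full(n_basis, h)


def make_dmp_weights(kind: BasisKind, w: np.ndarray) -> DMPWeights:
    """Attach weights (D, N) to the default kernel grid."""
    w = np.atleast_2d(np.asarray(w, dtype=float))
    means, bw = dmp_grid(kind, w.shape[1])
    return DMPWeights(kind=kind, w=w, means=means, bandwidths=bw)


def forcing_dmp(x: float, weights: DMPWeights, normalize: bool = True) -> np.ndarray:
    """Classic forcing: (normalized) kernel mixture, gated by ``s`` for the
    discrete kind.  ``normalize=False`` gives the plain weighted kernel sum
    used by the special-case equivalence."""
    if weights.kind is BasisKind.DISCRETE:
        psi = np.exp(-((x - weights.means) ** 2) / (2.0 * weights.bandwidths**2))
        gate = x
    else:
        psi = np.exp(weights.bandwidths * (np.cos(x - weights.means) - 1.0))
        gate = 1.0
    num = weights.w @ psi
    if not normalize:
        return num * gate
    denom = psi.sum()
    if denom < 1e-300:
        raise DegenerateNormalizerError(f"kernel normalizer vanished at phase {x}")
    return num / denom * gate


def forcing_synergies(
    x: float,
    k: int,
    shapes: list[SynergyShape],
    coeffs: TaskCoefficients,
    d: int | None = None,
):
    """Superposition of shared synergies for task ``k`` at phase ``x``.

    per_dimension: sum_m beta[m,k,d] * Lambda(x; theta[m,d], shift[m,k,d]),
    gated by ``x`` for the discrete kind.  time_varying: scalar beta[m,k] and
    a single shift[m,k] applied inside every kernel, shared across dimensions
    (the trailing discrete gate stays at the unshifted phase so the forcing
    still vanishes with the phase).  Returns a vector over dimensions, or a
    scalar when ``d`` is given.
    """
    if not shapes:
        raise SchemeMismatchError("need at least one synergy shape")
    kind = shapes[0].kind
    n_dims = shapes[0].n_dims
    M = len(shapes)
    if any(s.kind is not kind or s.n_dims != n_dims for s in shapes):
        raise SchemeMismatchError("all synergy shapes must share kind and D")
    if coeffs.n_synergies != M:
        raise SchemeMismatchError("coefficient M does not match number of shapes")
    if not 0 <= k < coeffs.n_tasks:
        raise IndexError(f"task index {k} out of range")
    per_dim = coeffs.scheme is CoefficientScheme.PER_DIMENSION
    if per_dim and coeffs.beta.shape[2] != n_dims:
        raise SchemeMismatchError("per-dimension beta D does not match shapes")

    f = np.zeros(n_dims)
    for m, shape in enumerate(shapes):
        if per_dim:
            shift = coeffs.dshift[m, k]          # (D,)
            beta = coeffs.beta[m, k]             # (D,)
        else:
            shift = coeffs.dshift[m, k]          # scalar, shared across dims
            beta = coeffs.beta[m, k]
        f += beta * eval_synergy_all_dims(x, shape, shift)
    if kind is BasisKind.DISCRETE:
        f = f * x
    if d is None:
        return f
    if not 0 <= d < n_dims:
        raise IndexError(f"dimension index {d} out of range")
    return float(f[d])


def dmp_as_special_case(weights: DMPWeights) -> tuple[list[SynergyShape], TaskCoefficients]:
    """Express a classic primitive as one shared synergy with unit weight.

    The returned pair satisfies ``forcing_synergies == forcing_dmp(...,
    normalize=False)`` at every phase: the synergy superposition carries no
    kernel normalizer.
    """
    D, N = weights.w.shape
    shape = SynergyShape(
        kind=weights.kind,
        amplitudes=weights.w.copy(),
        means=np.broadcast_to(weights.means, (D, N)).copy(),
        bandwidths=np.broadcast_to(weights.bandwidths, (D, N)).copy(),
    )
    coeffs = TaskCoefficients(
        scheme=CoefficientScheme.DMP_SPECIAL_CASE,
        beta=np.ones((1, 1)),
        dshift=np.zeros((1, 1)),
        learn_shifts=False,
    )
    return [shape], coeffs


@dataclass
class PrimitiveTrajectory:
    """Desired trajectory from integrating the attractor over the horizon."""

    t: np.ndarray        # (T,)
    y: np.ndarray        # (T, D)
    ydot: np.ndarray     # (T, D)
    phase: np.ndarray    # (T,)


def rollout_primitive(
    cfg: PrimitiveConfig,
    forcing=None,
    k: int = 0,
    y0=None,
    z0=None,
) -> PrimitiveTrajectory:
    """Integrate phase and attractor for ``cfg.n_steps`` steps.

    ``forcing`` is a callable ``(phase_value, k) -> per-DoF array`` or None
    for the unforced system.  The state is recorded before each update, so
    row 0 is the initial condition.  Deterministic given its inputs.
    """
    D = cfg.n_dims
    y0 = np.zeros(D) if y0 is None else np.broadcast_to(np.asarray(y0, float), (D,)).copy()
    z0 = np.zeros(D) if z0 is None else np.broadcast_to(np.asarray(z0, float), (D,)).copy()
    state = AttractorState(y0, z0)
    phase = initial_phase(cfg)
    T = cfg.n_steps
    y = np.empty((T, D))
    ydot = np.empty((T, D))
    ph = np.empty(T)
    for t in range(T):
        y[t] = state.y
        ydot[t] = state.ydot(cfg.tau)
        ph[t] = phase.value
        f = 0.0 if forcing is None else forcing(phase.value, k)
        state = step_attractor(state, f, cfg)
        phase = step_phase(phase, cfg)
    return PrimitiveTrajectory(t=np.arange(T) * cfg.dt, y=y, ydot=ydot, phase=ph)
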