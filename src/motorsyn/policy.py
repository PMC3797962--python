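"""Policy vector layout, multi-task objective and episodic policy search.

The flat policy vector concatenates the task-specific coefficients (all
mixing weights beta, then all time shifts if they are learned) and the
shared synergy parameters (amplitude, mean, bandwidth per kernel, per
dimension, per synergy).  Search is covariance matrix adaptation on the
summed multi-task cost estimated by rollouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .basis import BasisKind, SynergyShape
from .cma import CMAES
from .errors import InvalidParameterError, SchemeMismatchError
from .primitives import CoefficientScheme, TaskCoefficients

TWO_PI = 2.0 * np.pi


class ParameterCounts(NamedTuple):
    task_specific: int
    shared: int
    total: int


def count_parameters(
    n_tasks: int,
    n_synergies: int,
    n_basis: int,
    n_dims: int,
    scheme: CoefficientScheme | str,
    learn_shifts: bool,
) -> ParameterCounts:
    """Free-parameter accounting for a coefficient-sharing configuration.

    Task-specific: one beta (and one shift if learned) per task and synergy —
    per dimension for the Hadamard scheme, scalar for the time-varying
    scheme.  Shared: amplitude, mean and bandwidth for each of the N kernels
    of each of the M synergies in each of the D dimensions.
    """
    if min(n_tasks, n_synergies, n_basis, n_dims) < 1:
        raise InvalidParameterError("counts must be positive integers")
    scheme = CoefficientScheme(scheme)
    per_pair = 1 + int(bool(learn_shifts))
    if scheme is CoefficientScheme.TIME_VARYING:
        task_specific = n_tasks * n_synergies * per_pair
    elif scheme is CoefficientScheme.PER_DIMENSION:
        task_specific = n_tasks * n_synergies * n_dims * per_pair
    elif scheme is CoefficientScheme.DMP_SPECIAL_CASE:
        task_specific = 0  # beta fixed to one, shifts fixed to zero
    else:  # pragma: no cover
        raise SchemeMismatchError(f"unknown scheme {scheme}")
    shared = 3 * n_basis * n_dims * n_synergies
    return ParameterCounts(task_specific, shared, task_specific + shared)


@dataclass
class ParameterLayout:
    """Bijection between the flat policy vector and (coefficients, shapes).

    Block order: all beta, then all shifts (only if ``learn_shifts``), then
    for each synergy m, dimension d, kernel n the triple (a, mu, h).  When
    ``frozen_shapes`` is set the vector covers only the task-specific blocks
    and unpack attaches the frozen shapes — the layout used for
    generalization to new tasks.
    """

    n_tasks: int
    n_synergies: int
    n_basis: int
    n_dims: int
    scheme: CoefficientScheme = CoefficientScheme.TIME_VARYING
    learn_shifts: bool = False
    kind: BasisKind = BasisKind.DISCRETE
    frozen_shapes: list[SynergyShape] | None = None
    beta_max: float = 20.0
    amp_max: float = 20.0
    bandwidth_min: float = 1e-3

    def __post_init__(self):
        self.scheme = CoefficientScheme(self.scheme)
        self.kind = BasisKind(self.kind)
        counts = count_parameters(
            self.n_tasks, self.n_synergies, self.n_basis, self.n_dims,
            self.scheme, self.learn_shifts,
        )
        self._counts = counts
        if self.frozen_shapes is not None:
            for s in self.frozen_shapes:
                if s.n_dims != self.n_dims or s.n_basis != self.n_basis:
                    raise SchemeMismatchError("frozen shapes inconsistent with layout")
            if len(self.frozen_shapes) != self.n_synergies:
                raise SchemeMismatchError("need one frozen shape per synergy")

    @property
    def counts(self) -> ParameterCounts:
        return self._counts

    @property
    def beta_shape(self) -> tuple:
        if self.scheme is CoefficientScheme.PER_DIMENSION:
            return (self.n_synergies, self.n_tasks, self.n_dims)
        return (self.n_synergies, self.n_tasks)

    @property
    def n_beta(self) -> int:
        return int(np.prod(self.beta_shape))

    @property
    def n_free(self) -> int:
        if self.frozen_shapes is not None:
            return self._counts.task_specific
        return self._counts.total

    def pack(self, coeffs: TaskCoefficients, shapes: Sequence[SynergyShape] | None = None) -> np.ndarray:
        if coeffs.beta.shape != self.beta_shape:
            raise SchemeMismatchError(
                f"beta shape {coeffs.beta.shape} does not match layout {self.beta_shape}"
            )
        blocks = [coeffs.beta.ravel()]
        if self.learn_shifts:
            blocks.append(coeffs.dshift.ravel())
        if self.frozen_shapes is None:
            if shapes is None or len(shapes) != self.n_synergies:
                raise SchemeMismatchError("need one shape per synergy")
            for s in shapes:
                tri = np.stack([s.amplitudes, s.means, s.bandwidths], axis=-1)  # (D, N, 3)
                blocks.append(tri.ravel())
        vec = np.concatenate(blocks)
        if len(vec) != self.n_free:
            raise SchemeMismatchError("packed length mismatch")
        return vec

    def unpack(self, vec: np.ndarray) -> tuple[TaskCoefficients, list[SynergyShape]]:
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.n_free,):
            raise SchemeMismatchError(
                f"flat vector length {vec.shape} != layout length {self.n_free}"
            )
        pos = 0
        beta = vec[pos : pos + self.n_beta].reshape(self.beta_shape).copy()
        pos += self.n_beta
        if self.learn_shifts:
            dshift = vec[pos : pos + self.n_beta].reshape(self.beta_shape).copy()
            pos += self.n_beta
        else:
            dshift = np.zeros(self.beta_shape)
        coeffs = TaskCoefficients(
            scheme=self.scheme, beta=beta, dshift=dshift, learn_shifts=self.learn_shifts
        )
        if self.frozen_shapes is not None:
            return coeffs, list(self.frozen_shapes)
        shapes = []
        block = 3 * self.n_dims * self.n_basis
        for _ in range(self.n_synergies):
            tri = vec[pos : pos + block].reshape(self.n_dims, self.n_basis, 3)
            pos += block
            shapes.append(
                SynergyShape(
                    kind=self.kind,
                    amplitudes=tri[..., 0].copy(),
                    means=tri[..., 1].copy(),
                    bandwidths=tri[..., 2].copy(),
                )
            )
        return coeffs, shapes

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Box bounds per flat coordinate: weights and amplitudes symmetric,
        means inside the phase range, bandwidths positive."""
        rhythmic = self.kind is BasisKind.RHYTHMIC
        shift_lim = np.pi if rhythmic else 0.5
        mu_hi = TWO_PI if rhythmic else 1.0
        h_hi = 50.0 if rhythmic else 1.0
        lo = [np.full(self.n_beta, -self.beta_max)]
        hi = [np.full(self.n_beta, self.beta_max)]
        if self.learn_shifts:
            lo.append(np.full(self.n_beta, -shift_lim))
            hi.append(np.full(self.n_beta, shift_lim))
        if self.frozen_shapes is None:
            tri_lo = np.tile([-self.amp_max, 0.0, self.bandwidth_min], self.n_dims * self.n_basis)
            tri_hi = np.tile([self.amp_max, mu_hi, h_hi], self.n_dims * self.n_basis)
            for _ in range(self.n_synergies):
                lo.append(tri_lo)
                hi.append(tri_hi)
        return np.concatenate(lo), np.concatenate(hi)

    def restrict_to_task_specific(self, shapes: Sequence[SynergyShape]) -> "ParameterLayout":
        """Layout over beta (and shifts) only, with the given shapes frozen."""
        return replace(self, frozen_shapes=list(shapes))


@dataclass
class OptimizerConfig:
    """Episodic-search settings: initial exploration rate, budget, seed."""

    sigma0: float = 0.5
    max_evals: int = 1000
    popsize: int | None = None
    seed: int = 0
    rollouts_per_eval: int = 1
    bound_penalty: float = 1e3
    failure_cost: float = 1e6

    def __post_init__(self):
        if not (self.sigma0 > 0 and self.max_evals >= 0):
            raise InvalidParameterError("sigma0 must be positive and budget non-negative")


@dataclass
class LearningCurve:
    """Per-evaluation trace of the search: current and best-so-far cost."""

    evaluations: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    current_cost: np.ndarray = field(default_factory=lambda: np.empty(0))
    best_cost: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "evaluation": self.evaluations,
                "best_cost": self.best_cost,
                "current_cost": self.current_cost,
            }
        )


def evaluate_multitask(
    theta: np.ndarray,
    layout: ParameterLayout,
    task_fns: Sequence[Callable],
    rng: np.random.Generator | int | None = None,
    rollouts_per_eval: int = 1,
    failure_cost: float = 1e6,
) -> float:
    """Summed multi-task cost of a flat policy vector.

    ``task_fns[k](shapes, coeffs, k, rng) -> float`` rolls out task k and
    returns its cost.  The sum over tasks is averaged over
    ``rollouts_per_eval`` independent noise draws.  A failed rollout
    contributes a large finite penalty, never an exception.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    coeffs, shapes = layout.unpack(theta)
    totals = []
    for _ in range(rollouts_per_eval):
        total = 0.0
        for k, fn in enumerate(task_fns):
            try:
                c = float(fn(shapes, coeffs, k, rng))
                if not np.isfinite(c):
                    c = failure_cost
            except Exception:
                c = failure_cost
            total += c
        totals.append(total)
    return float(np.mean(totals))


def cma_optimize(
    objective: Callable[[np.ndarray], float],
    x0: np.ndarray,
    cfg: OptimizerConfig,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, LearningCurve]:
    """Minimize a scalar objective with CMA-ES inside an evaluation budget.

    Candidates are projected into the box for evaluation; the distance to
    the box enters the ranking as a quadratic penalty.  Returns the
    best-so-far (projected) point and the learning curve.  Reproducible
    given ``cfg.seed``.
    """
    x0 = np.asarray(x0, dtype=float)
    if not np.all(np.isfinite(x0)):
        raise InvalidParameterError("initial point must be finite")
    if bounds is not None:
        lo, hi = bounds
        x0 = np.clip(x0, lo, hi)
    es = CMAES(x0, cfg.sigma0, seed=cfg.seed, popsize=cfg.popsize)

    evals, cur, best = [], [], []
    best_x = x0.copy()
    best_c = np.inf
    n_evals = 0
    if cfg.max_evals == 0:
        c0 = float(objective(x0))
        return best_x, LearningCurve(np.array([0]), np.array([c0]), np.array([c0]))
    while n_evals < cfg.max_evals:
        cands = es.ask()
        ranked_costs = np.empty(len(cands))
        for i, x in enumerate(cands):
            if n_evals >= cfg.max_evals:
                ranked_costs[i] = np.inf  # not evaluated; worst rank
                continue
            if bounds is not None:
                xe = np.clip(x, lo, hi)
                pen = cfg.bound_penalty * float(np.sum((x - xe) ** 2))
            else:
                xe, pen = x, 0.0
            c = float(objective(xe))
            ranked_costs[i] = c + pen
            n_evals += 1
            if c < best_c:
                best_c = c
                best_x = xe.copy()
            evals.append(n_evals)
            cur.append(c)
            best.append(best_c)
        finite = np.isfinite(ranked_costs)
        if finite.sum() >= 2:
            worst = ranked_costs[finite].max()
            ranked_costs[~finite] = worst + 1.0
            es.tell(cands, ranked_costs)
    curve = LearningCurve(np.asarray(evals), np.asarray(cur), np.asarray(best))
    return best_x, curve


def make_multitask_objective(
    layout: ParameterLayout,
    task_fns: Sequence[Callable],
    cfg: OptimizerConfig,
) -> Callable[[np.ndarray], float]:
    """Objective closure with a deterministic per-evaluation noise stream."""
    counter = {"i": 0}

    def objective(theta: np.ndarray) -> float:
        rng = np.random.default_rng((cfg.seed, counter["i"]))
        counter["i"] += 1
        return evaluate_multitask(
            theta, layout, task_fns,
            rng=rng,
            rollouts_per_eval=cfg.rollouts_per_eval,
            failure_cost=cfg.failure_cost,
        )

    return objective


def optimize_policy(
    layout: ParameterLayout,
    task_fns: Sequence[Callable],
    cfg: OptimizerConfig,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, LearningCurve]:
    """End-to-end policy search over the full layout."""
    if x0 is None:
        x0 = default_initial_policy(layout, seed=cfg.seed)
    objective = make_multitask_objective(layout, task_fns, cfg)
    return cma_optimize(objective, x0, cfg, bounds=layout.bounds())


def generalize_fixed_synergies(
    shapes: Sequence[SynergyShape],
    task_fns: Sequence[Callable],
    layout: ParameterLayout,
    cfg: OptimizerConfig,
    x0: np.ndarray | None = None,
) -> tuple[TaskCoefficients, LearningCurve]:
    """Learn only task-specific coefficients with the synergies frozen.

    The number of free parameters equals the task-specific component of
    ``count_parameters``.  Returns the fitted coefficients and the curve.
    """
    restricted = layout.restrict_to_task_specific(shapes)
    if x0 is None:
        x0 = np.zeros(restricted.n_free)
    objective = make_multitask_objective(restricted, task_fns, cfg)
    best, curve = cma_optimize(objective, x0, cfg, bounds=restricted.bounds())
    coeffs, _ = restricted.unpack(best)
    return coeffs, curve


def default_initial_policy(layout: ParameterLayout, seed: int = 0) -> np.ndarray:
    """Small random amplitudes and grid-spread means; zero weights/shifts.

    Symmetry between synergies is broken by the seeded draw; bandwidths
    start at a quarter of the phase range.
    """
    rng = np.random.default_rng(seed)
    vec = np.zeros(layout.n_free)
    if layout.frozen_shapes is not None:
        return vec
    rhythmic = layout.kind is BasisKind.RHYTHMIC
    span = TWO_PI if rhythmic else 1.0
    pos = layout.n_beta * (2 if layout.learn_shifts else 1)
    for _ in range(layout.n_synergies):
        for _d in range(layout.n_dims):
            for n in range(layout.n_basis):
                a = 0.1 * rng.standard_normal()
                mu = (n + 0.5) / layout.n_basis * span + 0.05 * span * rng.standard_normal()
                h = 0.25 * span if not rhythmic else 2.0
                vec[pos : pos + 3] = [a, mu % span, h]
                pos += 3
    return vec
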