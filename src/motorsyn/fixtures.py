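"""Synthetic excitation patterns with known ground truth, and recovery.

The generator runs the synergy superposition forward on a phase grid for
every task and muscle and adds Gaussian noise — the statistical structure
the representation assumes in multi-muscle excitation data.  The recovery
routines solve the inverse problem with the shapes known: closed-form least
squares in the mixing weights for fixed time shifts, and a grid search over
shifts with an inner least-squares fit when the shifts are free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import SynergyShape, eval_synergy
from .errors import InvalidParameterError, RankDeficiencyError
from .primitives import BasisKind, CoefficientScheme, TaskCoefficients, forcing_synergies


@dataclass
class SyntheticPatternSet:
    """Ground truth plus generated per-task, per-muscle excitation traces."""

    shapes: list[SynergyShape]
    coeffs: TaskCoefficients
    grid: np.ndarray            # (T,) phase values
    sigma: float
    patterns: np.ndarray        # (K, T, D)
    seed: int | None
    clipped: bool = False

    @property
    def n_tasks(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_dims(self) -> int:
        return self.patterns.shape[2]


def generate_patterns(
    shapes: list[SynergyShape],
    coeffs: TaskCoefficients,
    grid: np.ndarray,
    sigma: float = 0.0,
    seed: int | None = 0,
    clip: bool = False,
) -> SyntheticPatternSet:
    """Noiseless forcing on the grid plus N(0, sigma^2) noise per sample."""
    grid = np.asarray(grid, dtype=float)
    K = coeffs.n_tasks
    D = shapes[0].n_dims
    patterns = np.empty((K, len(grid), D))
    for k in range(K):
        for t, s in enumerate(grid):
            patterns[k, t] = forcing_synergies(s, k, shapes, coeffs)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        patterns = patterns + rng.normal(0.0, sigma, size=patterns.shape)
    if clip:
        patterns = np.clip(patterns, 0.0, 1.0)
    return SyntheticPatternSet(
        shapes=shapes, coeffs=coeffs, grid=grid, sigma=sigma,
        patterns=patterns, seed=seed, clipped=clip,
    )


@dataclass
class RecoveredCoefficients:
    beta: np.ndarray
    dshift: np.ndarray
    residual: float
    scheme: CoefficientScheme


def _design_matrix(shapes, grid, shifts, scheme, n_dims):
    """Stacked regressor columns: one column per synergy (time-varying) or
    per (synergy, dimension) (per-dimension), rows over (sample, muscle)."""
    discrete = shapes[0].kind is BasisKind.DISCRETE
    gate = grid if discrete else np.ones_like(grid)
    M = len(shapes)
    cols = []
    for m, shape in enumerate(shapes):
        block = np.empty((len(grid), n_dims))
        for d in range(n_dims):
            shift = shifts[m] if np.isscalar(shifts[m]) else shifts[m][d]
            block[:, d] = eval_synergy(grid, shape, d, shift) * gate
        cols.append(block)
    if scheme is CoefficientScheme.TIME_VARYING:
        return np.stack([c.ravel() for c in cols], axis=1)  # (T*D, M)
    # per-dimension weights: block-diagonal over dimensions, rows ordered (t, d)
    X = np.zeros((len(grid) * n_dims, M * n_dims))
    for m, block in enumerate(cols):
        for d in range(n_dims):
            rows = np.arange(len(grid)) * n_dims + d
            X[rows, m * n_dims + d] = block[:, d]
    return X


def _lstsq_beta(X, y, n_params):
    sol, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < n_params:
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {n_params}; synergies are not "
            "distinguishable on this grid"
        )
    resid = float(np.linalg.norm(X @ sol - y))
    return sol, resid


def recover_coefficients(
    patterns: SyntheticPatternSet,
    shapes: list[SynergyShape],
    shift_grid: np.ndarray | None = None,
) -> RecoveredCoefficients:
    """Fit mixing weights (and optionally shifts) to generated patterns.

    With ``shift_grid`` None the shifts are fixed at zero and the weights
    are the exact least-squares solution per task.  With a grid, every
    combination of candidate shifts (one per synergy) is scored by its inner
    least-squares residual and the best is kept — exact when the true shift
    lies on the grid and the noise is zero.
    """
    if shapes[0].n_dims != patterns.n_dims:
        raise InvalidParameterError("shapes do not match pattern dimensions")
    scheme = patterns.coeffs.scheme
    if scheme is CoefficientScheme.DMP_SPECIAL_CASE:
        scheme = CoefficientScheme.TIME_VARYING
    K = patterns.n_tasks
    D = patterns.n_dims
    M = len(shapes)
    grid = patterns.grid
    n_beta = M if scheme is CoefficientScheme.TIME_VARYING else M * D

    beta_shape = (M, K) if scheme is CoefficientScheme.TIME_VARYING else (M, K, D)
    beta = np.zeros(beta_shape)
    dshift = np.zeros(beta_shape)
    total_resid = 0.0

    from itertools import product

    candidates = [np.zeros(M)] if shift_grid is None else [
        np.asarray(c) for c in product(shift_grid, repeat=M)
    ]
    for k in range(K):
        y = patterns.patterns[k].ravel()  # (T*D,) rows ordered (t, d)
        best = None
        for cand in candidates:
            X = _design_matrix(shapes, grid, cand, scheme, D)
            try:
                sol, resid = _lstsq_beta(X, y, n_beta)
            except RankDeficiencyError:
                if shift_grid is None:
                    raise
                continue
            if best is None or resid < best[2]:
                best = (sol, cand, resid)
        if best is None:
            raise RankDeficiencyError("all candidate shifts gave a deficient design")
        sol, cand, resid = best
        if scheme is CoefficientScheme.TIME_VARYING:
            beta[:, k] = sol
            dshift[:, k] = cand
        else:
            beta[:, k, :] = sol.reshape(M, D)
            dshift[:, k, :] = cand[:, None]
        total_resid += resid**2
    return RecoveredCoefficients(
        beta=beta, dshift=dshift, residual=float(np.sqrt(total_resid)), scheme=scheme
    )


def normalize_shapes(shapes: list[SynergyShape], coeffs: TaskCoefficients):
    """Resolve the beta-amplitude scale ambiguity for recovery comparisons.

    Each synergy's amplitude array is scaled to unit maximum absolute value
    and the scale is absorbed into its mixing weights.
    """
    new_shapes, scales = [], []
    for s in shapes:
        scale = float(np.max(np.abs(s.amplitudes)))
        if scale == 0:
            scale = 1.0
        new_shapes.append(
            SynergyShape(
                kind=s.kind,
                amplitudes=s.amplitudes / scale,
                means=s.means.copy(),
                bandwidths=s.bandwidths.copy(),
            )
        )
        scales.append(scale)
    scales = np.asarray(scales)
    beta = coeffs.beta * scales.reshape((-1,) + (1,) * (coeffs.beta.ndim - 1))
    new_coeffs = TaskCoefficients(
        scheme=coeffs.scheme, beta=beta, dshift=coeffs.dshift.copy(),
        learn_shifts=coeffs.learn_shifts,
    )
    return new_shapes, new_coeffs
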