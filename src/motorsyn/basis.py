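"""Parametrized basis functions and synergies.

A *synergy* is a superposition of ``N`` parametrized kernels per actuator
dimension: Gaussians in the decaying phase ``s`` for discrete movements, von
Mises bumps in the cyclic phase ``phi`` for rhythmic movements.  Each kernel
carries an amplitude ``a``, a mean ``mu`` and a bandwidth ``h``; the whole
synergy can be rigidly shifted in phase, which is how time-varying synergies
are realized downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import InvalidParameterError

TWO_PI = 2.0 * np.pi


class BasisKind(str, Enum):
    """Kernel family: decaying-phase Gaussians or cyclic von Mises bumps."""

    DISCRETE = "discrete"
    RHYTHMIC = "rhythmic"


@dataclass(frozen=True)
class BasisFunctionParams:
    """One kernel: amplitude (dimensionless), mean (phase units), bandwidth.

    For the discrete kind the bandwidth is a standard-deviation-like width in
    phase units; for the rhythmic kind it is a von Mises concentration.  The
    bandwidth must be strictly positive.
    """

    amplitude: float
    mean: float
    bandwidth: float

    def __post_init__(self):
        if not self.bandwidth > 0:
            raise InvalidParameterError(
                f"bandwidth must be positive, got {self.bandwidth}"
            )


def eval_gaussian(s, p: BasisFunctionParams, shift: float = 0.0):
    """Shifted Gaussian kernel ``a * exp(-(s - mu + shift)^2 / (2 h^2))``.

    ``s`` may be a scalar or an array; the shift is added inside the kernel
    argument without wrapping.
    """
    if not p.bandwidth > 0:
        raise InvalidParameterError("bandwidth must be positive")
    arg = np.asarray(s, dtype=float) - p.mean + shift
    return p.amplitude * np.exp(-(arg**2) / (2.0 * p.bandwidth**2))


def eval_von_mises(phi, p: BasisFunctionParams, shift: float = 0.0):
    """Shifted von Mises kernel ``a * exp(h * (cos(phi - mu + shift) - 1))``.

    The exponent is ``h * (cos(.) - 1)`` so the kernel is bounded by the
    amplitude and 2*pi-periodic; maximal at ``phi = mu - shift`` (mod 2*pi).
    """
    if not p.bandwidth > 0:
        raise InvalidParameterError("bandwidth must be positive")
    arg = np.asarray(phi, dtype=float) - p.mean + shift
    return p.amplitude * np.exp(p.bandwidth * (np.cos(arg) - 1.0))


@dataclass
class SynergyShape:
    """Task-invariant synergy shape: per-dimension kernel parameter arrays.

    ``amplitudes``, ``means`` and ``bandwidths`` all have shape ``(D, N)``
    where ``D`` is the number of actuator dimensions and ``N`` the number of
    kernels per dimension.  Rhythmic means are stored modulo 2*pi.
    """

    kind: BasisKind
    amplitudes: np.ndarray
    means: np.ndarray
    bandwidths: np.ndarray

    def __post_init__(self):
        self.kind = BasisKind(self.kind)
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.bandwidths = np.atleast_2d(np.asarray(self.bandwidths, dtype=float))
        if not (self.amplitudes.shape == self.means.shape == self.bandwidths.shape):
            raise InvalidParameterError(
                "amplitudes, means and bandwidths must share one (D, N) shape"
            )
        if self.amplitudes.ndim != 2 or self.amplitudes.size == 0:
            raise InvalidParameterError("need D >= 1 dimensions and N >= 1 kernels")
        if np.any(self.bandwidths <= 0):
            raise InvalidParameterError("all bandwidths must be positive")
        if self.kind is BasisKind.RHYTHMIC:
            self.means = np.mod(self.means, TWO_PI)

    @property
    def n_dims(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_basis(self) -> int:
        return self.amplitudes.shape[1]

    def basis_params(self, d: int) -> list[BasisFunctionParams]:
        """Kernel parameter objects for dimension ``d`` (0-based)."""
        return [
            BasisFunctionParams(self.amplitudes[d, n], self.means[d, n], self.bandwidths[d, n])
            for n in range(self.n_basis)
        ]

    @classmethod
    def from_params(cls, kind, per_dimension: list[list[BasisFunctionParams]]):
        a = np.array([[p.amplitude for p in row] for row in per_dimension])
        mu = np.array([[p.mean for p in row] for row in per_dimension])
        h = np.array([[p.bandwidth for p in row] for row in per_dimension])
        return cls(kind=kind, amplitudes=a, means=mu, bandwidths=h)


def eval_synergy(x, shape: SynergyShape, d: int, shift: float = 0.0):
    """Value of the synergy for dimension ``d`` at (shifted) phase ``x``.

    Sum over the ``N`` kernels of the dimension.  The shift is added inside
    every kernel argument; for the discrete kind this realizes the identity
    ``Lambda(s, shift) == Lambda(s + shift, 0)``.
    """
    if not 0 <= d < shape.n_dims:
        raise IndexError(f"dimension index {d} out of range for D={shape.n_dims}")
    x = np.asarray(x, dtype=float)
    arg = x[..., None] - shape.means[d] + shift
    if shape.kind is BasisKind.DISCRETE:
        vals = shape.amplitudes[d] * np.exp(-(arg**2) / (2.0 * shape.bandwidths[d] ** 2))
    else:
        vals = shape.amplitudes[d] * np.exp(shape.bandwidths[d] * (np.cos(arg) - 1.0))
    return vals.sum(axis=-1)


def eval_synergy_all_dims(x: float, shape: SynergyShape, shift) -> np.ndarray:
    """Synergy values for every dimension at one phase; ``shift`` is scalar
    or a per-dimension array."""
    shift = np.broadcast_to(np.asarray(shift, dtype=float), (shape.n_dims,))
    arg = x - shape.means + shift[:, None]
    if shape.kind is BasisKind.DISCRETE:
        vals = shape.amplitudes * np.exp(-(arg**2) / (2.0 * shape.bandwidths**2))
    else:
        vals = shape.amplitudes * np.exp(shape.bandwidths * (np.cos(arg) - 1.0))
    return vals.sum(axis=1)
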