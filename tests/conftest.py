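import numpy as np
import pytest

from motorsyn.basis import BasisKind, SynergyShape
from motorsyn.primitives import CoefficientScheme, TaskCoefficients


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_shape(rng, kind=BasisKind.DISCRETE, n_dims=3, n_basis=2):
    span = 2 * np.pi if kind is BasisKind.RHYTHMIC else 1.0
    return SynergyShape(
        kind=kind,
        amplitudes=rng.uniform(-1.5, 1.5, size=(n_dims, n_basis)),
        means=rng.uniform(0, span, size=(n_dims, n_basis)),
        bandwidths=rng.uniform(0.05, 0.4, size=(n_dims, n_basis))
        if kind is BasisKind.DISCRETE
        else rng.uniform(0.5, 5.0, size=(n_dims, n_basis)),
    )


def random_coeffs(rng, scheme, n_synergies, n_tasks, n_dims=None, learn_shifts=True, shift_scale=0.2):
    scheme = CoefficientScheme(scheme)
    shape = (
        (n_synergies, n_tasks, n_dims)
        if scheme is CoefficientScheme.PER_DIMENSION
        else (n_synergies, n_tasks)
    )
    return TaskCoefficients(
        scheme=scheme,
        beta=rng.uniform(-1.5, 1.5, size=shape),
        dshift=rng.uniform(-shift_scale, shift_scale, size=shape) if learn_shifts else None,
        learn_shifts=learn_shifts,
    )
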