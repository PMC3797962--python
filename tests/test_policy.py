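"""Parameter accounting, flat-vector bijection, CMA-ES behavior."""

import numpy as np
import pytest

from motorsyn.basis import BasisKind
from motorsyn.errors import InvalidParameterError, SchemeMismatchError
from motorsyn.policy import (
    OptimizerConfig,
    ParameterLayout,
    cma_optimize,
    count_parameters,
    default_initial_policy,
    evaluate_multitask,
    generalize_fixed_synergies,
    make_multitask_objective,
)
from motorsyn.primitives import CoefficientScheme

from conftest import random_coeffs, random_shape


class TestCounts:
    def test_viapoint_configuration_totals_eleven(self):
        c = count_parameters(5, 1, 2, 1, "per_dimension", learn_shifts=False)
        assert c == (5, 6, 11)

    @pytest.mark.parametrize(
        "m,expected",
        [(1, (12, 33, 45)), (2, (24, 66, 90)), (3, (36, 99, 135)),
         (4, (48, 132, 180)), (5, (60, 165, 225))],
    )
    def test_time_varying_muscle_configurations(self, m, expected):
        c = count_parameters(6, m, 1, 11, "time_varying", learn_shifts=True)
        assert tuple(c) == expected

    def test_per_dimension_with_shifts(self):
        c = count_parameters(4, 2, 3, 4, "per_dimension", learn_shifts=True)
        assert c.task_specific == 4 * 2 * 4 * 2
        assert c.shared == 3 * 3 * 4 * 2

    def test_invalid_counts_raise(self):
        with pytest.raises(InvalidParameterError):
            count_parameters(0, 1, 1, 1, "time_varying", False)


class TestLayout:
    @pytest.mark.parametrize("scheme,learn_shifts,kind", [
        ("per_dimension", False, BasisKind.DISCRETE),
        ("per_dimension", True, BasisKind.DISCRETE),
        ("time_varying", True, BasisKind.RHYTHMIC),
    ])
    def test_pack_unpack_roundtrip(self, scheme, learn_shifts, kind, rng):
        M, K, D, N = 2, 3, 4, 2
        layout = ParameterLayout(K, M, N, D, scheme, learn_shifts, kind)
        shapes = [random_shape(rng, kind=kind, n_dims=D, n_basis=N) for _ in range(M)]
        coeffs = random_coeffs(rng, scheme, M, K, n_dims=D, learn_shifts=learn_shifts)
        vec = layout.pack(coeffs, shapes)
        assert len(vec) == layout.counts.total
        coeffs2, shapes2 = layout.unpack(vec)
        np.testing.assert_array_equal(coeffs.beta, coeffs2.beta)
        np.testing.assert_array_equal(coeffs.dshift, coeffs2.dshift)
        for a, b in zip(shapes, shapes2):
            np.testing.assert_array_equal(a.amplitudes, b.amplitudes)
            np.testing.assert_array_equal(a.means, b.means)
            np.testing.assert_array_equal(a.bandwidths, b.bandwidths)
        # vector-level identity too
        np.testing.assert_array_equal(vec, layout.pack(coeffs2, shapes2))

    def test_perturbing_one_coordinate_changes_one_parameter(self, rng):
        layout = ParameterLayout(2, 2, 2, 3, "time_varying", True)
        vec = np.abs(rng.standard_normal(layout.counts.total)) + 0.5
        for i in (0, layout.n_beta, 2 * layout.n_beta):
            bumped = vec.copy()
            bumped[i] += 0.25
            c1, s1 = layout.unpack(vec)
            c2, s2 = layout.unpack(bumped)
            n_changed = (
                np.sum(c1.beta != c2.beta)
                + np.sum(c1.dshift != c2.dshift)
                + sum(
                    np.sum(a.amplitudes != b.amplitudes)
                    + np.sum(a.means != b.means)
                    + np.sum(a.bandwidths != b.bandwidths)
                    for a, b in zip(s1, s2)
                )
            )
            assert n_changed == 1

    def test_length_mismatch_raises(self):
        layout = ParameterLayout(2, 1, 1, 1, "time_varying", False)
        with pytest.raises(SchemeMismatchError):
            layout.unpack(np.zeros(layout.counts.total + 1))

    def test_restricted_layout_counts(self, rng):
        """Frozen-synergy generalization frees only the task block."""
        layout = ParameterLayout(6, 4, 1, 11, "time_varying", True)
        shapes = [random_shape(rng, n_dims=11, n_basis=1) for _ in range(4)]
        restricted = layout.restrict_to_task_specific(shapes)
        assert restricted.n_free == 48 == layout.counts.task_specific
        single = ParameterLayout(1, 1, 1, 1, "time_varying", False)
        restricted1 = single.restrict_to_task_specific(
            [random_shape(rng, n_dims=1, n_basis=1)]
        )
        assert restricted1.n_free == 1


class TestEvaluate:
    def _quadratic_tasks(self, layout, K):
        def make(k):
            def fn(shapes, coeffs, kk, rng):
                return float(np.sum((coeffs.beta[:, kk] - (kk + 1)) ** 2))

            return fn

        return [make(k) for k in range(K)]

    def test_single_task_reduces_to_task_cost(self):
        layout = ParameterLayout(1, 1, 1, 1, "time_varying", False)
        fns = self._quadratic_tasks(layout, 1)
        theta = layout.pack(*_coeffs_shapes(layout, beta=0.0))
        assert evaluate_multitask(theta, layout, fns) == pytest.approx(1.0)

    def test_deterministic_without_noise(self):
        layout = ParameterLayout(3, 1, 1, 1, "time_varying", False)
        fns = self._quadratic_tasks(layout, 3)
        theta = layout.pack(*_coeffs_shapes(layout, beta=0.5))
        assert evaluate_multitask(theta, layout, fns, rng=0) == evaluate_multitask(
            theta, layout, fns, rng=1
        )

    def test_failure_becomes_finite_penalty(self):
        layout = ParameterLayout(1, 1, 1, 1, "time_varying", False)

        def boom(shapes, coeffs, k, rng):
            raise RuntimeError("rollout failed")

        theta = layout.pack(*_coeffs_shapes(layout, beta=0.0))
        val = evaluate_multitask(theta, layout, [boom], failure_cost=1e6)
        assert val == 1e6

    def test_more_rollouts_reduce_variance(self):
        layout = ParameterLayout(1, 1, 1, 1, "time_varying", False)

        def noisy(shapes, coeffs, k, rng):
            return float(rng.normal())

        theta = layout.pack(*_coeffs_shapes(layout, beta=0.0))

        def variance(n_rollouts):
            vals = [
                evaluate_multitask(theta, layout, [noisy], rng=i, rollouts_per_eval=n_rollouts)
                for i in range(20)
            ]
            return np.var(vals)

        assert variance(8) < variance(1)


class TestCMA:
    def test_sphere_converges(self):
        """Quadratic oracle: 10-D sphere from the all-ones start."""
        best, curve = cma_optimize(
            lambda x: float(np.sum(x**2)),
            np.ones(10),
            OptimizerConfig(sigma0=0.5, max_evals=5000, seed=1),
        )
        assert np.sum(best**2) < 1e-8
        assert curve.evaluations[-1] <= 5000

    def test_best_curve_non_increasing(self):
        _, curve = cma_optimize(
            lambda x: float(np.sum((x - 2) ** 2)),
            np.zeros(5),
            OptimizerConfig(sigma0=0.3, max_evals=600, seed=2),
        )
        assert np.all(np.diff(curve.best_cost) <= 0)

    def test_never_worse_than_start_on_deterministic_objective(self):
        f = lambda x: float(np.sum(x**4) + 1.0)
        x0 = np.full(4, 1.3)
        best, _ = cma_optimize(f, x0, OptimizerConfig(sigma0=0.2, max_evals=400, seed=3))
        assert f(best) <= f(x0)

    def test_zero_budget_returns_initial(self):
        x0 = np.array([1.0, -2.0])
        best, curve = cma_optimize(
            lambda x: float(np.sum(x**2)), x0, OptimizerConfig(sigma0=0.5, max_evals=0, seed=0)
        )
        np.testing.assert_array_equal(best, x0)

    def test_reproducible_given_seed(self):
        f = lambda x: float(np.sum(x**2))
        cfg = OptimizerConfig(sigma0=0.5, max_evals=300, seed=42)
        a, ca = cma_optimize(f, np.ones(6), cfg)
        b, cb = cma_optimize(f, np.ones(6), cfg)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(ca.current_cost, cb.current_cost)

    def test_bounds_respected(self):
        lo, hi = np.full(3, -0.5), np.full(3, 0.5)
        best, _ = cma_optimize(
            lambda x: float(np.sum((x - 2) ** 2)),
            np.zeros(3),
            OptimizerConfig(sigma0=0.5, max_evals=400, seed=0),
            bounds=(lo, hi),
        )
        assert np.all(best <= hi + 1e-12) and np.all(best >= lo - 1e-12)
        np.testing.assert_allclose(best, hi, atol=1e-3)


class TestGeneralization:
    def test_frozen_synergy_beta_recovery_matches_least_squares(self, rng):
        """With shapes frozen and a quadratic pattern-matching objective the
        optimum found by the search agrees with the least-squares oracle."""
        from motorsyn.primitives import forcing_synergies

        layout = ParameterLayout(2, 1, 2, 2, "time_varying", False)
        shapes = [random_shape(rng, n_dims=2, n_basis=2)]
        true_coeffs = random_coeffs(rng, "time_varying", 1, 2, learn_shifts=False)
        grid = np.linspace(1.0, 0.05, 25)
        target = {
            k: np.array([forcing_synergies(s, k, shapes, true_coeffs) for s in grid])
            for k in range(2)
        }

        def make(k):
            def fn(sh, coeffs, kk, rng_):
                pred = np.array([forcing_synergies(s, kk, sh, coeffs) for s in grid])
                return float(np.sum((pred - target[kk]) ** 2))

            return fn

        cfg = OptimizerConfig(sigma0=0.5, max_evals=1500, seed=5)
        coeffs, curve = generalize_fixed_synergies(shapes, [make(k) for k in range(2)], layout, cfg)
        np.testing.assert_allclose(coeffs.beta, true_coeffs.beta, atol=5e-3)
        assert np.all(np.diff(curve.best_cost) <= 0)


def _coeffs_shapes(layout, beta):
    from motorsyn.primitives import TaskCoefficients

    coeffs = TaskCoefficients(
        scheme=layout.scheme, beta=np.full(layout.beta_shape, float(beta))
    )
    shapes = [
        random_shape(np.random.default_rng(0), kind=layout.kind, n_dims=layout.n_dims,
                     n_basis=layout.n_basis)
        for _ in range(layout.n_synergies)
    ]
    return coeffs, shapes
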