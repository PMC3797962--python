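"""Synthetic-pattern generation, coefficient recovery, file IO and CLI."""

import numpy as np
import pytest
from click.testing import CliRunner

from motorsyn.basis import BasisKind, SynergyShape
from motorsyn.cli import main
from motorsyn.environments import EpisodeResult
from motorsyn.errors import RankDeficiencyError, TrajectoryParseError
from motorsyn.fixtures import (
    generate_patterns,
    normalize_shapes,
    recover_coefficients,
)
from motorsyn.io import (
    ExperimentConfig,
    load_policy,
    read_trajectory_csv,
    save_policy,
    write_trajectory_csv,
)
from motorsyn.primitives import CoefficientScheme, TaskCoefficients, forcing_synergies

from conftest import random_coeffs, random_shape


def _truth(rng, M=2, K=3, D=2, learn_shifts=False):
    shapes = [
        SynergyShape(
            kind=BasisKind.DISCRETE,
            amplitudes=rng.uniform(0.4, 1.2, size=(D, 2)),
            means=rng.uniform(0.15 + 0.4 * m, 0.35 + 0.4 * m, size=(D, 2)),
            bandwidths=rng.uniform(0.06, 0.12, size=(D, 2)),
        )
        for m in range(M)
    ]
    coeffs = TaskCoefficients(
        scheme=CoefficientScheme.TIME_VARYING,
        beta=rng.uniform(0.5, 1.5, size=(M, K)),
        dshift=rng.choice([-0.1, 0.0, 0.1], size=(M, K)) if learn_shifts else None,
        learn_shifts=learn_shifts,
    )
    return normalize_shapes(shapes, coeffs)


class TestGenerate:
    def test_noiseless_patterns_equal_forcing(self, rng):
        shapes, coeffs = _truth(rng)
        grid = np.linspace(1.0, 0.02, 30)
        ps = generate_patterns(shapes, coeffs, grid, sigma=0.0)
        for k in range(coeffs.n_tasks):
            for i, s in enumerate(grid):
                np.testing.assert_allclose(
                    ps.patterns[k, i], forcing_synergies(s, k, shapes, coeffs)
                )

    def test_same_seed_identical(self, rng):
        shapes, coeffs = _truth(rng)
        grid = np.linspace(1.0, 0.02, 20)
        a = generate_patterns(shapes, coeffs, grid, sigma=0.1, seed=5)
        b = generate_patterns(shapes, coeffs, grid, sigma=0.1, seed=5)
        np.testing.assert_array_equal(a.patterns, b.patterns)

    def test_zero_weights_zero_patterns(self, rng):
        shapes, coeffs = _truth(rng)
        coeffs = TaskCoefficients(scheme=coeffs.scheme, beta=np.zeros_like(coeffs.beta))
        ps = generate_patterns(shapes, coeffs, np.linspace(1, 0.02, 10), sigma=0.0)
        assert np.all(ps.patterns == 0.0)


class TestRecover:
    def test_zero_noise_fixed_shift_recovery_is_exact(self, rng):
        shapes, coeffs = _truth(rng)
        grid = np.linspace(1.0, 0.02, 60)
        ps = generate_patterns(shapes, coeffs, grid, sigma=0.0)
        fit = recover_coefficients(ps, shapes)
        assert np.max(np.abs(fit.beta - coeffs.beta) / np.abs(coeffs.beta)) < 1e-6

    def test_zero_noise_free_shift_recovery_on_grid(self, rng):
        shapes, coeffs = _truth(rng, M=1, learn_shifts=True)
        grid = np.linspace(1.0, 0.02, 60)
        ps = generate_patterns(shapes, coeffs, grid, sigma=0.0)
        shift_grid = np.array([-0.2, -0.1, 0.0, 0.1, 0.2])
        fit = recover_coefficients(ps, shapes, shift_grid=shift_grid)
        np.testing.assert_allclose(fit.dshift, coeffs.dshift, atol=1e-12)
        np.testing.assert_allclose(fit.beta, coeffs.beta, rtol=1e-6)

    def test_zero_patterns_give_zero_beta(self, rng):
        shapes, coeffs = _truth(rng)
        grid = np.linspace(1.0, 0.02, 30)
        ps = generate_patterns(shapes, coeffs, grid, sigma=0.0)
        ps.patterns[:] = 0.0
        fit = recover_coefficients(ps, shapes)
        np.testing.assert_allclose(fit.beta, 0.0, atol=1e-12)

    def test_rank_deficiency_reported(self, rng):
        shape = random_shape(rng, n_dims=2, n_basis=2)
        shapes = [shape, shape]  # identical synergies: unidentifiable
        coeffs = TaskCoefficients(
            scheme=CoefficientScheme.TIME_VARYING, beta=np.ones((2, 1))
        )
        ps = generate_patterns(shapes, coeffs, np.linspace(1, 0.02, 30), sigma=0.0)
        with pytest.raises(RankDeficiencyError):
            recover_coefficients(ps, shapes)

    def test_recovery_error_decreases_with_noise(self, rng):
        """Median relative error over 20 seeds is monotone in sigma."""
        shapes, coeffs = _truth(rng)
        grid = np.linspace(1.0, 0.02, 60)
        med = {}
        for sigma in (0.0, 0.01, 0.1):
            errs = []
            for seed in range(20):
                ps = generate_patterns(shapes, coeffs, grid, sigma=sigma, seed=seed)
                fit = recover_coefficients(ps, shapes)
                errs.append(np.linalg.norm(fit.beta - coeffs.beta) / np.linalg.norm(coeffs.beta))
            med[sigma] = np.median(errs)
        assert med[0.0] <= med[0.01] <= med[0.1]


class TestTrajectoryCSV:
    def _episode(self):
        rng = np.random.default_rng(0)
        T, D = 17, 3
        return EpisodeResult(
            y=rng.standard_normal((T, D)),
            ydot=rng.standard_normal((T, D)),
            u=rng.standard_normal((T - 1, D)),
            phase=np.linspace(1, 0.01, T),
            extras={"impact": rng.random(T - 1) > 0.7},
        )

    def test_roundtrip_is_lossless(self, tmp_path):
        res = self._episode()
        path = tmp_path / "traj.csv"
        write_trajectory_csv(res, path, dt=0.002)
        back = read_trajectory_csv(path)
        np.testing.assert_array_equal(back.y, res.y)
        np.testing.assert_array_equal(back.ydot, res.ydot)
        np.testing.assert_array_equal(back.u, res.u)
        np.testing.assert_array_equal(back.phase, res.phase)

    def test_empty_trajectory_roundtrip(self, tmp_path):
        res = EpisodeResult(y=np.empty((0, 1)), ydot=np.empty((0, 1)))
        path = tmp_path / "empty.csv"
        write_trajectory_csv(res, path)
        back = read_trajectory_csv(path)
        assert back.n_steps == 0

    def test_truncated_file_names_line(self, tmp_path):
        res = self._episode()
        path = tmp_path / "traj.csv"
        write_trajectory_csv(res, path)
        lines = path.read_text().splitlines()
        lines[5] = lines[5].split(",")[0]  # drop all but one field in row 5
        bad = tmp_path / "bad.csv"
        bad.write_text("\n".join(lines))
        with pytest.raises(TrajectoryParseError) as exc:
            read_trajectory_csv(bad)
        assert exc.value.line is not None


class TestConfigAndPolicy:
    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = ExperimentConfig(environment="pointmass", n_tasks=5, seed=7)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = ExperimentConfig.from_yaml(path)
        assert back == cfg
        assert back.digest() == cfg.digest()

    def test_unknown_field_rejected_with_name(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("environment: pointmass\nbogus_field: 3\n")
        with pytest.raises(Exception, match="bogus_field"):
            ExperimentConfig.from_yaml(path)

    def test_policy_yaml_roundtrip(self, tmp_path, rng):
        shapes, coeffs = _truth(rng)
        path = tmp_path / "policy.yaml"
        save_policy(path, coeffs, shapes)
        coeffs2, shapes2 = load_policy(path)
        np.testing.assert_array_equal(coeffs.beta, coeffs2.beta)
        np.testing.assert_array_equal(shapes[0].means, shapes2[0].means)


class TestCLI:
    def test_count_prints_accounting(self):
        runner = CliRunner()
        res = runner.invoke(
            main,
            ["count", "-K", "6", "-M", "4", "-N", "1", "-D", "11",
             "--scheme", "time_varying", "--learn-shifts"],
        )
        assert res.exit_code == 0
        assert "task_specific=48 shared=132 total=180" in res.output

    def test_unknown_subcommand_fails_with_usage(self):
        runner = CliRunner()
        res = runner.invoke(main, ["frobnicate"])
        assert res.exit_code != 0
        assert "Usage" in res.output or "No such command" in res.output

    def test_learn_with_zero_budget_returns_initial_policy(self, tmp_path):
        cfg = ExperimentConfig(environment="pointmass", max_evals=0, seed=3,
                               output_dir=str(tmp_path / "out"))
        cfg_path = tmp_path / "cfg.yaml"
        cfg.to_yaml(cfg_path)
        runner = CliRunner()
        res = runner.invoke(main, ["learn", "--config", str(cfg_path)])
        assert res.exit_code == 0, res.output
        coeffs, shapes = load_policy(tmp_path / "out" / "policy.yaml")
        from motorsyn.policy import default_initial_policy

        layout = cfg.layout()
        expected_coeffs, expected_shapes = layout.unpack(
            np.clip(default_initial_policy(layout, seed=3), *layout.bounds())
        )
        np.testing.assert_array_equal(coeffs.beta, expected_coeffs.beta)
        np.testing.assert_array_equal(shapes[0].means, expected_shapes[0].means)

    def test_rollout_writes_trajectories_and_report(self, tmp_path):
        cfg = ExperimentConfig(environment="pointmass", seed=1,
                               output_dir=str(tmp_path / "out"))
        cfg_path = tmp_path / "cfg.yaml"
        cfg.to_yaml(cfg_path)
        runner = CliRunner()
        res = runner.invoke(main, ["rollout", "--config", str(cfg_path)])
        assert res.exit_code == 0, res.output
        out = tmp_path / "out"
        assert (out / "cost_report.csv").exists()
        traj = read_trajectory_csv(out / "trajectory_task0.csv")
        assert traj.n_steps == cfg.n_steps

    def test_invalid_config_nonzero_exit(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("environment: mars_rover\n")
        runner = CliRunner()
        res = runner.invoke(main, ["learn", "--config", str(path)])
        assert res.exit_code != 0
        assert "environment" in res.output
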