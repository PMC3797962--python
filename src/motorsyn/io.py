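"""Experiment configuration and CSV/YAML serialization.

Configs are flat YAML key trees with four blocks (task, primitive,
controller, optimizer); trajectories and learning curves are CSV files
written at 17 significant digits so the numeric round trip is lossless.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .basis import BasisKind, SynergyShape
from .environments import EpisodeResult
from .errors import InvalidParameterError, TrajectoryParseError
from .policy import OptimizerConfig, ParameterLayout, count_parameters
from .primitives import CoefficientScheme, TaskCoefficients

_FLOAT_FMT = "%.17g"


@dataclass
class ExperimentConfig:
    """Everything a run needs: task set, primitive structure, controller,
    optimizer settings and output paths."""

    environment: str = "pointmass"        # pointmass | walker | arm
    n_tasks: int = 5
    n_synergies: int = 1
    n_basis: int = 2
    n_dims: int = 1
    scheme: str = "per_dimension"
    learn_shifts: bool = False
    kind: str = "discrete"
    alpha_z: float = 2.0
    beta_z: float = 0.9
    tau: float = 0.1
    alpha_s: float | None = None
    dt: float = 0.01
    n_steps: int = 50
    k_pos: float = 400.0
    k_vel: float = 15.0
    tau_rise: float = 0.010
    tau_fall: float = 0.040
    sigma0: float = 0.5
    max_evals: int = 1000
    popsize: int | None = None
    seed: int = 0
    rollouts_per_eval: int = 1
    output_dir: str = "results"
    task_options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.environment not in ("pointmass", "walker", "arm"):
            raise InvalidParameterError(
                f"environment: unknown value {self.environment!r}"
            )
        # raises on inconsistent counts before any run starts
        count_parameters(
            self.n_tasks, self.n_synergies, self.n_basis, self.n_dims,
            self.scheme, self.learn_shifts,
        )
        BasisKind(self.kind)
        CoefficientScheme(self.scheme)

    def layout(self) -> ParameterLayout:
        return ParameterLayout(
            n_tasks=self.n_tasks,
            n_synergies=self.n_synergies,
            n_basis=self.n_basis,
            n_dims=self.n_dims,
            scheme=self.scheme,
            learn_shifts=self.learn_shifts,
            kind=self.kind,
        )

    def optimizer(self) -> OptimizerConfig:
        return OptimizerConfig(
            sigma0=self.sigma0,
            max_evals=self.max_evals,
            popsize=self.popsize,
            seed=self.seed,
            rollouts_per_eval=self.rollouts_per_eval,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise InvalidParameterError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(
                f"{path}: unknown config field(s) {sorted(unknown)}"
            )
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


# --- policy serialization -------------------------------------------------


def save_policy(path, coeffs: TaskCoefficients, shapes: list[SynergyShape]) -> None:
    data = {
        "scheme": coeffs.scheme.value,
        "learn_shifts": bool(coeffs.learn_shifts),
        "beta": coeffs.beta.tolist(),
        "dshift": coeffs.dshift.tolist(),
        "shapes": [
            {
                "kind": s.kind.value,
                "amplitudes": s.amplitudes.tolist(),
                "means": s.means.tolist(),
                "bandwidths": s.bandwidths.tolist(),
            }
            for s in shapes
        ],
    }
    Path(path).write_text(yaml.safe_dump(data))


def load_policy(path) -> tuple[TaskCoefficients, list[SynergyShape]]:
    data = yaml.safe_load(Path(path).read_text())
    shapes = [
        SynergyShape(
            kind=s["kind"],
            amplitudes=np.array(s["amplitudes"]),
            means=np.array(s["means"]),
            bandwidths=np.array(s["bandwidths"]),
        )
        for s in data["shapes"]
    ]
    coeffs = TaskCoefficients(
        scheme=data["scheme"],
        beta=np.array(data["beta"]),
        dshift=np.array(data["dshift"]),
        learn_shifts=data["learn_shifts"],
    )
    return coeffs, shapes


# --- trajectory CSV -------------------------------------------------------


def write_trajectory_csv(result: EpisodeResult, path, dt: float = 1.0) -> None:
    """Column schema: step, time, y_d..., ydot_d..., u_d.../excitation_d...,
    phase, impact."""
    y = np.atleast_2d(np.asarray(result.y, dtype=float))
    if y.shape[0] == 1 and np.asarray(result.y).ndim == 1:
        y = y.T
    ydot = np.atleast_2d(np.asarray(result.ydot, dtype=float))
    if ydot.shape[0] == 1 and np.asarray(result.ydot).ndim == 1:
        ydot = ydot.T
    T, D = y.shape
    frame = {"step": np.arange(T), "time": np.arange(T) * dt}
    for d in range(D):
        frame[f"y_{d}"] = y[:, d]
    for d in range(ydot.shape[1]):
        frame[f"ydot_{d}"] = ydot[:, d]
    if result.u is not None:
        u = np.atleast_2d(np.asarray(result.u, dtype=float))
        if u.shape[0] == 1 and np.asarray(result.u).ndim == 1:
            u = u.T
        for d in range(u.shape[1]):
            col = np.full(T, np.nan)
            col[: len(u)] = u[:, d]
            frame[f"u_{d}"] = col
    if result.excitations is not None:
        e = np.asarray(result.excitations, dtype=float)
        for d in range(e.shape[1]):
            frame[f"excitation_{d}"] = e[:, d]
    if result.phase is not None:
        frame[f"phase"] = np.asarray(result.phase, dtype=float)[:T]
    if "impact" in result.extras:
        col = np.zeros(T)
        flags = np.asarray(result.extras["impact"], dtype=float)
        col[: len(flags)] = flags
        frame["impact"] = col
    pd.DataFrame(frame).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory_csv(path) -> EpisodeResult:
    """Inverse of :func:`write_trajectory_csv`; raises with the offending
    line number on malformed input."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pandas reports the line itself
        raise TrajectoryParseError(str(exc)) from exc
    except pd.errors.EmptyDataError as exc:
        raise TrajectoryParseError("file is empty") from exc
    required = {"step", "time"}
    if not required <= set(df.columns):
        raise TrajectoryParseError(f"missing required columns {required - set(df.columns)}")
    for col in df.columns:
        bad = df[col].isna()
        if col.startswith("u_"):
            bad = bad[:-1] if len(bad) else bad  # last control row is absent by design
        if bad.any():
            raise TrajectoryParseError(
                f"non-numeric or missing value in column {col!r}",
                line=int(np.argmax(bad.values)) + 2,
            )
    y_cols = sorted((c for c in df.columns if c.startswith("y_")), key=lambda c: int(c[2:]))
    yd_cols = sorted((c for c in df.columns if c.startswith("ydot_")), key=lambda c: int(c[5:]))
    u_cols = sorted((c for c in df.columns if c.startswith("u_")), key=lambda c: int(c[2:]))
    e_cols = sorted((c for c in df.columns if c.startswith("excitation_")), key=lambda c: int(c[11:]))
    y = df[y_cols].to_numpy()
    ydot = df[yd_cols].to_numpy()
    u = df[u_cols].to_numpy()[:-1] if u_cols else None
    if y.shape[1] == 1:
        y, ydot = y[:, 0], ydot[:, 0]
        if u is not None:
            u = u[:, 0]
    extras = {}
    if "impact" in df.columns:
        extras["impact"] = df["impact"].to_numpy().astype(bool)
    return EpisodeResult(
        y=y,
        ydot=ydot,
        u=u,
        excitations=df[e_cols].to_numpy() if e_cols else None,
        phase=df["phase"].to_numpy() if "phase" in df.columns else None,
        extras=extras,
    )


def write_learning_curve_csv(curve, path) -> None:
    curve.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_cost_report_csv(rows: list[dict], path) -> None:
    """One row per task: k, total and the individual cost terms."""
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
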