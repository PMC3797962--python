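"""Wire configurations to environments: build task evaluators for search.

Each builder returns ``(layout, task_fns, aux)`` where ``task_fns[k]`` maps
``(shapes, coeffs, k, rng)`` to the scalar cost of task ``k`` — the shape
expected by :func:`motorsyn.policy.evaluate_multitask`.
"""

from __future__ import annotations

import numpy as np

from .basis import BasisKind
from .control import ControllerGains
from .environments import (
    ArmTask,
    PointMassTask,
    WalkerTask,
    arm_rollout,
    pointmass_rollout,
    viapoint_cost,
    walker_cost,
    walker_rollout,
)
from .environments.arm import reaching_task_cost
from .errors import InvalidParameterError
from .io import ExperimentConfig
from .policy import ParameterLayout
from .primitives import PrimitiveConfig, forcing_synergies, rollout_primitive


def _forcing(shapes, coeffs):
    return lambda s, k: forcing_synergies(s, k, shapes, coeffs)


def build_pointmass(config: ExperimentConfig):
    task = PointMassTask(
        n_steps=config.n_steps,
        dt=config.dt,
        gains=ControllerGains(config.k_pos, config.k_vel),
        **config.task_options,
    )
    cfg = PrimitiveConfig(
        alpha_z=config.alpha_z,
        beta_z=config.beta_z,
        tau=config.tau,
        goal=task.goal,
        dt=task.dt,
        n_steps=task.n_steps,
        kind=BasisKind.DISCRETE,
        alpha_s=config.alpha_s,
    )

    def make_fn(k):
        def fn(shapes, coeffs, kk, rng):
            desired = rollout_primitive(cfg, _forcing(shapes, coeffs), kk)
            result = pointmass_rollout(task, desired, rng)
            return viapoint_cost(result, task, kk)

        return fn

    layout = config.layout()
    if layout.n_tasks != task.n_tasks:
        raise InvalidParameterError("n_tasks does not match number of via-points")
    return layout, [make_fn(k) for k in range(task.n_tasks)], {"task": task, "primitive": cfg}


def build_walker(config: ExperimentConfig):
    task = WalkerTask(**config.task_options)
    cfg = PrimitiveConfig(
        alpha_z=config.alpha_z,
        beta_z=config.beta_z,
        tau=config.tau,
        goal=task.goal,
        dt=task.dt,
        n_steps=task.max_steps,
        kind=BasisKind.RHYTHMIC,
    )

    def make_fn(k):
        def fn(shapes, coeffs, kk, rng):
            result = walker_rollout(task, cfg, _forcing(shapes, coeffs), kk, rng)
            return walker_cost(result, task, kk)

        return fn

    layout = config.layout()
    if layout.n_dims != 4 or layout.kind is not BasisKind.RHYTHMIC:
        raise InvalidParameterError("walker experiments need rhythmic primitives with D=4")
    if layout.n_tasks != task.n_tasks:
        raise InvalidParameterError("n_tasks does not match number of step heights")
    return layout, [make_fn(k) for k in range(task.n_tasks)], {"task": task, "primitive": cfg}


def build_arm(config: ExperimentConfig):
    task = ArmTask(n_steps=config.n_steps, dt=config.dt, **config.task_options)
    cfg = PrimitiveConfig(
        alpha_z=config.alpha_z,
        beta_z=config.beta_z,
        tau=config.tau,
        goal=np.zeros(task.n_muscles),
        dt=task.dt,
        n_steps=task.n_steps,
        kind=BasisKind.DISCRETE,
        alpha_s=config.alpha_s,
    )

    def make_fn(k):
        def fn(shapes, coeffs, kk, rng):
            result = arm_rollout(task, _forcing(shapes, coeffs), kk, rng, cfg=cfg)
            return reaching_task_cost(result, task, kk)

        return fn

    layout = config.layout()
    if layout.n_dims != task.n_muscles:
        raise InvalidParameterError("n_dims must equal the muscle count")
    if layout.n_tasks != task.n_tasks:
        raise InvalidParameterError("n_tasks does not match number of targets")
    return layout, [make_fn(k) for k in range(task.n_tasks)], {"task": task, "primitive": cfg}


_BUILDERS = {"pointmass": build_pointmass, "walker": build_walker, "arm": build_arm}


def build_experiment(config: ExperimentConfig):
    return _BUILDERS[config.environment](config)
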