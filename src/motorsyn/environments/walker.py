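"""Planar 5-link biped walker with hybrid dynamics.

The robot is a kinematic tree pinned at the stance foot: stance shank and
thigh, torso, swing thigh and shank.  Only the two hips and the two knees
are actuated; the orientation of the whole chain relative to the ground is
an unactuated degree of freedom, so the walker is underactuated.  When the
swing foot hits the ground an instantaneous inelastic impact is applied and
the legs swap roles.  During closed-loop walking the rhythmic phase is reset
to zero at every impact so the gait cycle locks to the contact events.

Internally the configuration is the vector of five absolute link angles
``phi`` (measured from the upward vertical; the link direction is
``d(phi) = (sin phi, cos phi)``), in the order stance shank, stance thigh,
torso, swing thigh, swing shank.  With absolute angles the mass matrix has
the closed form ``M(phi) = W * cos(phi_j - phi_k) + diag(I)`` for a constant
coupling matrix ``W``, and the Coriolis vector reduces to
``(W * sin(phi_j - phi_k)) @ phid**2``, so no numerical differentiation is
needed anywhere in the dynamics.

The physical parameters (masses, lengths, limits, gains, initial state) are
documented defaults in the style of standard five-link planar walkers; they
parametrize the benchmark, they are not measurements of any particular
robot.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..control import ControllerGains, feedback_control
from ..errors import InvalidParameterError
from ..primitives import BasisKind, PhaseState, PrimitiveConfig, initial_phase, step_attractor, step_phase, AttractorState
from . import EpisodeResult

# rows: link index (stance shank, stance thigh, torso, swing thigh, swing shank)
# cols: which absolute angle contributes, with its lever arm, to the link COM.
_N_LINKS = 5

# Maps torques on the 4 actuated relative joints (stance hip, swing hip,
# stance knee, swing knee) to generalized forces on phi:  Q = A.T @ tau with
# q_rel = A @ phi (up to constant offsets).
_A_ACT = np.array(
    [
        [0.0, 1.0, -1.0, 0.0, 0.0],   # stance hip   = phi1 - phi2
        [0.0, 0.0, -1.0, 1.0, 0.0],   # swing hip    = phi3 - pi - phi2
        [1.0, -1.0, 0.0, 0.0, 0.0],   # stance knee  = phi0 - phi1
        [0.0, 0.0, 0.0, -1.0, 1.0],   # swing knee   = phi4 - phi3
    ]
)


@dataclass
class WalkerParams:
    """Link masses (kg), lengths (m), COM fractions and rod inertias."""

    m_shank: float = 3.2
    m_thigh: float = 6.8
    m_torso: float = 12.0
    l_shank: float = 0.4
    l_thigh: float = 0.4
    l_torso: float = 0.625
    gravity: float = 9.81

    def __post_init__(self):
        for name in ("m_shank", "m_thigh", "m_torso", "l_shank", "l_thigh", "l_torso"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive")
        # lever-arm table: com_i = base + sum_j R[i, j] * d(phi_j)
        ls, lt, lb = self.l_shank, self.l_thigh, self.l_torso
        cs, ct, cb = 0.5 * ls, 0.5 * lt, 0.5 * lb
        self._R = np.array(
            [
                [cs, 0.0, 0.0, 0.0, 0.0],
                [ls, ct, 0.0, 0.0, 0.0],
                [ls, lt, cb, 0.0, 0.0],
                [ls, lt, 0.0, ct, 0.0],
                [ls, lt, 0.0, lt, cs],
            ]
        )
        self._masses = np.array(
            [self.m_shank, self.m_thigh, self.m_torso, self.m_thigh, self.m_shank]
        )
        self._inertias = np.array(
            [
                self.m_shank * ls**2 / 12.0,
                self.m_thigh * lt**2 / 12.0,
                self.m_torso * lb**2 / 12.0,
                self.m_thigh * lt**2 / 12.0,
                self.m_shank * ls**2 / 12.0,
            ]
        )
        # constant coupling matrix W_jk = sum_i m_i R[i,j] R[i,k]
        self._W = self._R.T @ (self._masses[:, None] * self._R)
        self._wg = self._masses @ self._R  # gravity lever weights, shape (5,)
        self._rfoot = np.array([ls, lt, 0.0, lt, ls])  # swing-foot levers
        self._m_total = float(self._masses.sum())


@dataclass
class WalkerState:
    """Pinned-chain state: absolute link angles, their rates, stance-foot x
    and a stance-leg label that flips at every impact."""

    phi: np.ndarray
    phid: np.ndarray
    base_x: float = 0.0
    stance: int = 0
    swing_cleared: bool = False  # True once the swing foot has lifted off

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float).copy()
        self.phid = np.asarray(self.phid, dtype=float).copy()
        if self.phi.shape != (_N_LINKS,) or self.phid.shape != (_N_LINKS,):
            raise InvalidParameterError("walker state needs 5 angles and 5 rates")

    def q(self) -> np.ndarray:
        """Interface coordinates [hip_st, hip_sw, knee_st, knee_sw, torso],
        each wrapped into (-pi, pi] (relative angles are only defined mod
        2*pi once the legs have been relabeled)."""
        p = self.phi
        raw = np.array([p[1] - p[2], p[3] - np.pi - p[2], p[0] - p[1], p[4] - p[3], p[2]])
        return np.mod(raw + np.pi, 2.0 * np.pi) - np.pi

    def qdot(self) -> np.ndarray:
        p = self.phid
        return np.array([p[1] - p[2], p[3] - p[2], p[0] - p[1], p[4] - p[3], p[2]])


def _default_initial_state() -> WalkerState:
    # mid-stance posture leaning forward, swing leg swinging through
    phi = np.array([0.12, 0.12, 0.02, np.pi - 0.32, np.pi - 0.42])
    phid = np.array([0.9, 0.9, 0.4, -1.2, -1.0])
    return WalkerState(phi=phi, phid=phid, base_x=0.0, stance=0, swing_cleared=False)


@dataclass
class WalkerTask:
    """Multi-gait benchmark: one desired step height per task."""

    step_heights: tuple = (0.15, 0.2, 0.25, 0.3)
    dt: float = 0.002
    max_steps: int = 5000
    sigma: float = 1.0
    params: WalkerParams = field(default_factory=WalkerParams)
    q_min: np.ndarray = field(
        default_factory=lambda: np.array([-1.6, -1.6, -2.8, -2.8, -1.1])
    )
    q_max: np.ndarray = field(
        default_factory=lambda: np.array([1.6, 1.6, 2.8, 2.8, 1.1])
    )
    gains: ControllerGains = field(
        default_factory=lambda: ControllerGains(np.full(4, 120.0), np.full(4, 8.0))
    )
    goal: np.ndarray = field(default_factory=lambda: np.array([0.25, -0.25, -0.15, -0.15]))
    initial_state: WalkerState = field(default_factory=_default_initial_state)

    def __post_init__(self):
        if any(r <= 0 for r in self.step_heights):
            raise InvalidParameterError("desired step heights must be positive")
        self.q_min = np.asarray(self.q_min, dtype=float)
        self.q_max = np.asarray(self.q_max, dtype=float)

    @property
    def n_tasks(self) -> int:
        return len(self.step_heights)

    def alive(self, state: WalkerState) -> bool:
        q = state.q()
        return bool(np.all(q >= self.q_min) and np.all(q <= self.q_max))


# --- kinematics -----------------------------------------------------------


def _dvec(phi):
    return np.stack([np.sin(phi), np.cos(phi)], axis=-1)


def joint_positions(state: WalkerState, params: WalkerParams) -> dict:
    """World positions of the foot, knees, hip, torso tip and swing foot."""
    d = _dvec(state.phi)
    base = np.array([state.base_x, 0.0])
    knee_st = base + params.l_shank * d[0]
    hip = knee_st + params.l_thigh * d[1]
    torso_tip = hip + params.l_torso * d[2]
    knee_sw = hip + params.l_thigh * d[3]
    foot_sw = knee_sw + params.l_shank * d[4]
    return {
        "stance_foot": base,
        "stance_knee": knee_st,
        "hip": hip,
        "torso_tip": torso_tip,
        "swing_knee": knee_sw,
        "swing_foot": foot_sw,
    }


def swing_foot_height(state: WalkerState, params: WalkerParams) -> float:
    return float(joint_positions(state, params)["swing_foot"][1])


def _com_positions(state: WalkerState, params: WalkerParams) -> np.ndarray:
    d = _dvec(state.phi)  # (5, 2)
    return np.array([state.base_x, 0.0]) + params._R @ d


def _com_velocities(phi, phid, params: WalkerParams) -> np.ndarray:
    dp = np.stack([np.cos(phi), -np.sin(phi)], axis=-1)  # d'(phi)
    return params._R @ (phid[:, None] * dp)


# --- pinned-chain dynamics ------------------------------------------------


def mass_matrix(phi: np.ndarray, params: WalkerParams) -> np.ndarray:
    dphi = phi[:, None] - phi[None, :]
    return params._W * np.cos(dphi) + np.diag(params._inertias)


def _dynamics(phi, phid, tau4, params: WalkerParams):
    """phidd for the pinned chain under actuated-joint torques tau4."""
    dphi = phi[:, None] - phi[None, :]
    M = params._W * np.cos(dphi) + np.diag(params._inertias)
    cor = (params._W * np.sin(dphi)) @ (phid**2)
    grav = -params.gravity * params._wg * np.sin(phi)
    rhs = _A_ACT.T @ tau4 - cor - grav
    return np.linalg.solve(M, rhs)


def mechanical_energy(state: WalkerState, params: WalkerParams) -> float:
    M = mass_matrix(state.phi, params)
    kin = 0.5 * state.phid @ M @ state.phid
    pot = params.gravity * float(params._masses @ _com_positions(state, params)[:, 1])
    return float(kin + pot)


# --- impact map -----------------------------------------------------------


def _extended_mass_matrix(phi, params: WalkerParams) -> np.ndarray:
    """Mass matrix with a floating base (coords [phi_0..4, bx, by])."""
    Me = np.zeros((7, 7))
    Me[:5, :5] = mass_matrix(phi, params)
    dp = np.stack([np.cos(phi), -np.sin(phi)], axis=-1)  # (5, 2)
    coupling = params._wg[:, None] * dp                   # (5, 2)
    Me[:5, 5:] = coupling
    Me[5:, :5] = coupling.T
    Me[5:, 5:] = params._m_total * np.eye(2)
    return Me


def _swing_foot_jacobian_ext(phi, params: WalkerParams) -> np.ndarray:
    J = np.zeros((2, 7))
    dp = np.stack([np.cos(phi), -np.sin(phi)], axis=-1)
    J[:, :5] = (params._rfoot[:, None] * dp).T
    J[:, 5:] = np.eye(2)
    return J


def angular_momentum_about(state: WalkerState, params: WalkerParams, point: np.ndarray) -> float:
    """z-component of the total angular momentum about a ground point."""
    coms = _com_positions(state, params)
    vels = _com_velocities(state.phi, state.phid, params)
    rel = coms - np.asarray(point, dtype=float)
    lz = np.sum(params._masses * (rel[:, 0] * vels[:, 1] - rel[:, 1] * vels[:, 0]))
    # link angles are measured clockwise from the vertical, so the CCW spin
    # rate of link i is -phid_i
    lz -= np.sum(params._inertias * state.phid)
    return float(lz)


def _apply_impact(state: WalkerState, params: WalkerParams) -> WalkerState:
    """Inelastic impact at the swing foot, then leg relabeling.

    The chain is momentarily treated as floating; the only impulse acts at
    the new contact point and brings its velocity to zero, so the total
    angular momentum about that point is conserved and kinetic energy can
    only decrease.
    """
    Me = _extended_mass_matrix(state.phi, params)
    Jc = _swing_foot_jacobian_ext(state.phi, params)
    v_minus = np.concatenate([state.phid, np.zeros(2)])
    MiJt = np.linalg.solve(Me, Jc.T)
    lam = -np.linalg.solve(Jc @ MiJt, Jc @ v_minus)
    v_plus = v_minus + MiJt @ lam
    phid_plus = v_plus[:5]

    foot = joint_positions(state, params)["swing_foot"]
    perm = [4, 3, 2, 1, 0]
    phi_new = state.phi[perm].copy()
    phi_new[[0, 1, 3, 4]] += np.pi  # leg links reverse proximal/distal roles
    phi_new = np.mod(phi_new + np.pi, 2.0 * np.pi) - np.pi
    phid_new = phid_plus[perm]
    return WalkerState(
        phi=phi_new,
        phid=phid_new,
        base_x=float(foot[0]),
        stance=1 - state.stance,
        swing_cleared=False,
    )


# --- stepping and rollout -------------------------------------------------

_CLEARANCE_ARM = 1e-3  # m the swing foot must rise before contact re-arms


def walker_step(state: WalkerState, torques, task: WalkerTask):
    """One RK4 step of the pinned dynamics, then contact handling.

    Returns ``(new_state, impact)``.  Contact fires when the swing foot,
    having cleared the ground since the last impact, crosses height zero
    moving downward; the impact map is applied instantaneously and the legs
    are relabeled.
    """
    tau = np.broadcast_to(np.asarray(torques, dtype=float), (4,))
    p = task.params
    dt = task.dt
    phi, phid = state.phi, state.phid

    def f(y):
        q, qd = y[:5], y[5:]
        return np.concatenate([qd, _dynamics(q, qd, tau, p)])

    y0 = np.concatenate([phi, phid])
    k1 = f(y0)
    k2 = f(y0 + 0.5 * dt * k1)
    k3 = f(y0 + 0.5 * dt * k2)
    k4 = f(y0 + dt * k3)
    y1 = y0 + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    new = WalkerState(
        phi=y1[:5],
        phid=y1[5:],
        base_x=state.base_x,
        stance=state.stance,
        swing_cleared=state.swing_cleared,
    )

    h = swing_foot_height(new, p)
    if not new.swing_cleared:
        if h > _CLEARANCE_ARM:
            new.swing_cleared = True
        return new, False
    dp4 = np.stack([np.cos(new.phi), -np.sin(new.phi)], axis=-1)
    vy = float((p._rfoot * new.phid) @ dp4[:, 1])
    if h <= 0.0 and vy < 0.0:
        return _apply_impact(new, p), True
    return new, False


def walker_rollout(
    task: WalkerTask,
    cfg: PrimitiveConfig,
    forcing,
    k: int,
    seed: int | np.random.Generator | None = 0,
    gains: ControllerGains | None = None,
) -> EpisodeResult:
    """Closed-loop walking episode with phase resetting.

    The rhythmic primitive (4 DoF: stance hip, swing hip, stance knee, swing
    knee) produces desired joint trajectories; a PD law plus Gaussian torque
    noise drives the walker.  At every swing-foot impact the phase is reset
    to zero and the maximal foot clearance of the finished step is recorded.
    The episode ends at the horizon or at the first joint-limit violation.
    """
    if cfg.kind is not BasisKind.RHYTHMIC:
        raise InvalidParameterError("walker control expects a rhythmic primitive")
    if cfg.n_dims != 4:
        raise InvalidParameterError("walker control needs D = 4")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gains = gains if gains is not None else task.gains
    p = task.params

    state = replace(task.initial_state)
    q0 = state.q()[:4]
    att = AttractorState(q0.copy(), np.zeros(4))
    phase = initial_phase(cfg)

    T = task.max_steps
    q_trace = np.empty((T + 1, 5))
    qd_trace = np.empty((T + 1, 5))
    u_trace = np.empty((T, 4))
    phase_trace = np.empty(T + 1)
    impact_flags = np.zeros(T, dtype=bool)
    hip_x = np.empty(T + 1)

    step_heights = []
    max_clearance = 0.0
    x1 = joint_positions(state, p)["hip"][0]
    n_alive = 0

    for t in range(T):
        q_trace[t] = state.q()
        qd_trace[t] = state.qdot()
        phase_trace[t] = phase.value
        hip_x[t] = joint_positions(state, p)["hip"][0]

        f = 0.0 if forcing is None else forcing(phase.value, k)
        att = step_attractor(att, f, cfg)
        u = feedback_control(att.y, att.ydot(cfg.tau), state.q()[:4], state.qdot()[:4], gains)
        tau = u + (rng.normal(0.0, task.sigma, size=4) if task.sigma > 0 else 0.0)
        u_trace[t] = tau

        state, impact = walker_step(state, tau, task)
        max_clearance = max(max_clearance, swing_foot_height(state, p))
        if impact:
            impact_flags[t] = True
            step_heights.append(max_clearance)
            max_clearance = 0.0
            phase = PhaseState(0.0)
        else:
            phase = step_phase(phase, cfg)
        n_alive = t + 1
        if not task.alive(state):
            break

    q_trace[n_alive] = state.q()
    qd_trace[n_alive] = state.qdot()
    phase_trace[n_alive] = phase.value
    hip_x[n_alive] = joint_positions(state, p)["hip"][0]
    n = n_alive
    return EpisodeResult(
        y=q_trace[: n + 1],
        ydot=qd_trace[: n + 1],
        u=u_trace[:n],
        phase=phase_trace[: n + 1],
        extras={
            "impact": impact_flags[:n],
            "step_heights": np.asarray(step_heights),
            "hip_x": hip_x[: n + 1],
            "x1": float(x1),
            "xT": float(hip_x[n]),
            "n_steps_alive": n,
        },
    )


def walker_cost(result: EpisodeResult, task: WalkerTask, k: int) -> float:
    """Walking cost: travelled hip distance (rewarded), time lived short of
    the 5 s horizon and squared deviations of step heights from the target,

        C(k) = -0.6 (x_T - x_1) + 0.2 (5 - T dt) + 50 sum_i (r_i - r*_k)^2.
    """
    ex = result.extras
    for key in ("x1", "xT", "n_steps_alive", "step_heights"):
        if key not in ex:
            raise InvalidParameterError(f"episode lacks record '{key}'")
    r_star = task.step_heights[k]
    heights = np.asarray(ex["step_heights"], dtype=float)
    return float(
        -0.6 * (ex["xT"] - ex["x1"])
        + 0.2 * (5.0 - ex["n_steps_alive"] * task.dt)
        + 50.0 * np.sum((heights - r_star) ** 2)
    )
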