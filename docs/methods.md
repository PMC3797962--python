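# Methods

This note records the models implemented in `motorsyn`, their assumptions,
the defaults that matter, and the choices made where the design was open.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Movement representation

**Attractor system.** Each actuator follows the damped-spring system
`tau z' = alpha_z (beta_z (g - y) - z) + f`, `tau y' = z`. The desired
velocity is *defined* as `z / tau` rather than integrated separately, so the
two never drift apart. Integration is explicit Euler at the environment time
step; correctness is established against the matrix-exponential solution of
the unforced linear system (global error is first order in `dt`), not by
fixing a particular scheme. With `beta_z <= alpha_z / 4` the system is
overdamped and converges monotonically; the benchmark defaults
(`alpha_z = 2`, `beta_z = 0.9` point mass, `beta_z = 0.5` walker) are
underdamped, as is usual for these primitives.

**Phase.** Discrete movements use `tau s' = -alpha_s s` with `s(0) = 1`;
rhythmic movements use `tau phi' = 1`. `alpha_s` defaults to
`tau ln(100) / (T dt)` so the phase has decayed to ~0.01 at the end of the
horizon; it is configurable.

**Synergy forcing.** A synergy is a per-dimension sum of `N` kernels —
Gaussians `a exp(-(s - mu + ds)^2 / (2 h^2))` in the decaying phase, von
Mises bumps `a exp(h (cos(phi - mu + ds) - 1))` in the cyclic phase. The von
Mises exponent is `h * (cos(.) - 1)`, the bounded convention; the alternative
reading `h cos(.) - 1` differs only by the constant factor `exp(h - 1)`
absorbed into the amplitude, and is not offered. Amplitudes may be negative;
non-negativity of muscle excitations is enforced downstream by clipping in
the plant, not in the representation.

Two coefficient-sharing schemes are implemented. *Per-dimension*: weights
and shifts indexed `(m, k, d)` (the Hadamard form). *Time-varying*: one
scalar weight and one shift per `(m, k)` applied identically to all
dimensions — a time-varying synergy displaced as a whole. In both schemes
the shift enters **inside the kernel argument only**; the trailing phase
gate of the discrete forcing stays at the unshifted `s`. This makes the two
schemes coincide exactly whenever their weights and shifts agree, and keeps
the discrete forcing vanishing as `s -> 0` so goal convergence is never
compromised by a shift. (Shifting the gate as well would break both
properties for a constant-factor change the weights can absorb.) No wrapping
is applied to discrete shifts; rhythmic means are stored modulo 2 pi.

**Classic primitives as a special case.** `dmp_as_special_case` maps a
fixed-grid weighted-kernel primitive onto a single synergy with unit weight.
The identity holds against the *unnormalized* classic forcing: the
normalized form divides by the kernel sum, while a synergy superposition has
no normalizer. `forcing_dmp` exposes both via its `normalize` flag; the
equivalence is tested with `normalize=False` to 1e-12. The default kernel
grid places `N` means equally spaced on `[0, 1]` (or `[0, 2 pi)`) with
bandwidths chosen so adjacent kernels intersect at half height.

## Control and muscle model

The feedback law is diagonal PD control on the desired trajectory. The
activation dynamics `a' = (e^2 - e a)/tau_rise + (e - a)/tau_fall`
(tau_rise = 10 ms, tau_fall = 40 ms) are integrated by explicit Euler at the
plant time step and clamped to [0, 1]; the steady state is `a = e` for any
constant excitation, and the rise is faster than the fall. Excitations are
clipped to [0, 1] *before* the activation ODE — synergy outputs can be
negative, and a signed excitation has no physiological meaning here.

## Benchmark plants

**Point mass (via-point task).** A 1 kg double integrator driven by PD
tracking (k_pos = 400, k_vel = 15) of the primitive's desired trajectory,
with N(0, 0.5^2) motor noise added to the commanded acceleration each step.
Horizon T = 50 at dt = 10 ms; five via-points {0.2, 0.1, 0, -0.1, -0.2};
goal g = 1. The via time index is not fixed by the task description and
defaults to mid-horizon (step 25). The cost is
`1e5 (y_tvp - vp)^2 + 1e4 (ydot_T^2 + 10 (y_T - g)^2) + 5e-4 * sum(u)`;
the control term is printed elsewhere as an unsquared sum, which rewards
negative accelerations, so the default penalizes `sum(u^2)` and the literal
form remains available as `control_penalty="as_printed"`. The penalty is
computed on the commanded (noise-free) control; the noise the policy cannot
control perturbs the plant instead.

**Planar 5-link biped walker.** Stance shank/thigh, torso, swing
thigh/shank, pinned at the stance foot; hips and knees actuated, ground
orientation free (underactuated). Internally the configuration is the five
*absolute* link angles, for which the mass matrix has the closed form
`W o cos(phi_j - phi_k) + diag(I)` with a constant coupling matrix `W`; the
Coriolis vector collapses to `(W o sin(phi_j - phi_k)) @ phid^2` and gravity
is diagonal, so the dynamics are fully analytic (validated against a
finite-difference Lagrangian, and by energy conservation to ~1e-10 relative
per 0.5 s of torque-free motion under RK4 at dt = 2 ms). Physical defaults
are standard five-link values (torso 12 kg / 0.625 m, thighs 6.8 kg / 0.4 m,
shanks 3.2 kg / 0.4 m, uniform rods); they are benchmark fixtures, not
measurements. Ground contact fires when the swing foot, having cleared
1 mm since the last impact (hysteresis against scuffing at lift-off),
crosses height zero moving downward. The impact is instantaneous and
inelastic: the chain is momentarily treated as floating, a single impulse at
the new contact zeroes that point's velocity, and the legs are relabeled.
This conserves angular momentum about the contact point exactly and can only
remove kinetic energy — both tested. The rhythmic phase is reset to zero at
every impact, locking the gait cycle to ground contacts. The controller
tracks role-indexed joints (stance hip, swing hip, stance knee, swing knee):
after relabeling, every step executes the same role-based pattern, the
symmetric-gait reading of the task. Episodes end at the horizon (5000 steps)
or at the first joint-limit violation; the cost is
`-0.6 (x_T - x_1) + 0.2 (5 - T dt) + 50 sum_i (r_i - r*)^2` with `r_i` the
maximal swing-foot clearance of step i.

**Muscle-actuated planar arm.** A stand-in plant: two hinge joints
(shoulder, elbow) in the sagittal plane, upper arm 0.30 m / 1.9 kg, forearm
0.33 m / 1.5 kg, standard two-link equations of motion; six lumped muscles
(mono-articular flexor/extensor at each joint plus a bi-articular pair) with
constant moment arms and force = activation x max isometric force; marker at
the wrist; six targets on a 15 cm circle around the initial marker position;
open loop, T = 500 at dt = 1 ms. The cost per target is three times the
time-averaged marker-target distance plus 1e-3 times the integral of the
squared excitation vector over the phase interval (trapezoid rule on the
recorded phase trace); the total objective sums over targets. Published
results that depend on an 11-muscle tendon-and-wrapping model are not
reproducible with this plant and are not targeted; the parameter accounting
for 11 muscles is independent of the plant and is reproduced exactly.

## Policy search

The flat policy vector concatenates all mixing weights, then all time shifts
(when learned), then per synergy the `(a, mu, h)` triples — a bijection
tested coordinate by coordinate. Bandwidths are kept positive by a box lower
bound (1e-3 in phase units) rather than a log reparametrization, so packing
and unpacking are exactly inverse. Means are bounded to the phase range,
weights and amplitudes to +/-20.

CMA-ES is the standard `(mu/mu_w, lambda)` strategy with cumulative
step-size adaptation and rank-1 plus rank-mu covariance updates; the default
population is `4 + floor(3 ln n)`. Candidates are projected into the box for
evaluation and the squared projection distance enters the ranking as a
penalty. A degenerate covariance (condition > 1e14 or non-finite state)
triggers a restart with the initial step size. One objective evaluation
rolls out every task once (rollouts-per-evaluation = 1 by default, matching
per-episode sample counting; configurable for variance reduction), sums the
task costs, and maps any rollout failure to a large finite penalty (1e6) so
the search never dies mid-run — truncated walker episodes are already
penalized by their own cost. For the noisy via-point study the population is
raised to 20: on noisy, multimodal objectives a larger population stabilizes
the ranking step, and across seeds it removed the occasional convergence to
a poor local optimum observed with the default population of 10.

Frozen-synergy generalization restricts the layout to the task-specific
blocks (the synergy shapes are attached as constants), so the free-parameter
count equals the task-specific component of the accounting — verified for
the published configurations.

Identifiability: `beta` and the amplitudes share a scale (only their product
matters). Recovery fixtures therefore normalize each synergy's amplitudes to
unit maximum absolute value and absorb the scale into `beta`; learning runs
impose no such constraint.

## Synthetic patterns and recovery

`generate_patterns` runs the forcing forward on a phase grid for every task
and muscle and adds i.i.d. Gaussian noise — the generative structure the
representation assumes, with known ground truth. It emulates the *shape*
statistics of multi-muscle excitation data (smooth bumps, shared timing
across muscles, task-specific scaling); it does not emulate EMG measurement
artifacts, rectification, or cross-muscle noise correlations, so passing
recovery tests demonstrates identifiability of the representation, not
robustness to real recording noise. With shifts fixed, recovery of `beta` is
closed-form least squares (exact at zero noise); with free shifts, candidate
shift combinations on a user grid are scored by their inner least-squares
residual. Rank deficiency (e.g. duplicate synergies) raises an error rather
than being silently regularized.

## Problem sizes and tolerances

Test and acceptance runs use the study conditions directly: T = 50 episodes
for the point-mass task with a 2000-evaluation budget; walker physics checks
use 0.5 s windows (250 steps at 2 ms); recovery uses 60-point grids and 20
noise seeds. Numerical tolerances follow the oracle in each case: 1e-12 for
algebraic identities, 1e-3 for first-order integrator agreement over a
second of simulated time, machine-precision checks for impact conservation
laws. Degenerate inputs are contracts, not silent fallbacks: non-positive
bandwidths, scheme/shape mismatches, vanishing kernel normalizers and
rank-deficient recovery designs all raise typed errors.

## Known limitations

- The arm omits tendon compliance, force-length/velocity scaling, wrapping
  geometry and noise; its learned excitation patterns are qualitative.
- The walker's ground model is a pure inelastic point impact: no slipping,
  no double-support phase, no ground compliance.
- The shift grid in free-shift recovery must contain the true shift to be
  exact; between grid points the error is bounded by the grid spacing times
  the pattern's slope.
- CMA-ES is a local stochastic search; multimodal landscapes (the walker
  especially) can retain seed-to-seed variability in the attained optimum.
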