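# Methods

This note documents the models, numerical methods and design choices behind
`sprintopt`, in the package's own terms.

## Scope and model

`sprintopt` studies how hypothetical technique modifications change
accelerative sprinting performance. The pipeline has four stages: a
synthetic-data generator producing dynamically consistent two-step sprint
trials, a data-tracking optimal control simulation that reproduces a trial
on a musculoskeletal model, a family of seven predictive simulations that
free chosen net joint moments while minimizing the horizon duration, and an
outcomes layer computing performance and technique measures.

The skeleton is a planar (sagittal) kinematic tree: a floating pelvis base
(anterior-posterior and vertical translation plus rotation) carrying a
lumped trunk+head segment, two thighs, two shanks and two feet; an optional
variant splits each foot at a metatarsophalangeal (MTP) joint carrying a
linear rotational spring (default 25 N m/rad). Default anthropometry scales
standard segment-mass and length fractions to a 72.2 kg, 1.79 m athlete.
Conventions: +x is the direction of travel, +y up, angles counter-clockwise
positive; hip flexion positive, knee flexion negative, ankle dorsiflexion
positive, forward trunk inclination negative.

Environment forces:

- **Foot-ground contact**: two smooth Hunt-Crossley spheres per foot
  (heel, forefoot; radius 2 cm). Normal force
  `k * pen^1.5 * (1 + d * pen_rate)` with `k = 3e6 N/m^1.5`, `d = 2 s/m`;
  the penetration passes through a softplus positive part (scale 1e-4 m) and
  the dissipation bracket through a square-root clamp so the force is C1 and
  complex-step differentiable everywhere. Tangential force is regularized
  Coulomb friction `-mu * Fn * tanh(v_slip / 0.05 m/s)` with `mu = 0.8`.
  These constants are configuration defaults: plausible values for sprint
  spikes on a hard track, chosen once.
- **Aerodynamic drag** `-0.5 rho Cd Af v|v|` applied at the whole-body CoM,
  with the frontal area estimated from stature and mass
  (`Af = 0.266 * 0.2025 * H^0.725 * M^0.425`), `Cd = 0.9`, `rho = 1.2 kg/m^3`.

Muscle-tendon units are three-element Hill models in the implicit
tendon-force-state form: states are the normalized tendon force and the
activation; the contraction dynamics enter as an algebraic equilibrium
residual (tendon force = pennation-projected active + passive fiber force),
and the activation dynamics as the pair of rate inequalities whose envelope
is exactly the bilinear first-order activation ODE with time constants 15 ms
(activation) and 60 ms (deactivation). Characteristic curves use the widely
published exponential-tendon / Gaussian-sum / logarithmic-force-velocity
parameterization (see `hill_constants.py`, version-tagged); the active
force-length and force-velocity curves are renormalized by their value at
the reference point so the anchors (1 at optimal length, 1 at zero velocity)
hold exactly. Musculotendon geometry uses separable per-coordinate
polynomials with moment arm = -dL/dq; the default planar set has eight MTUs
per leg with representative adult parameters.

The actuator map assigns each internal coordinate one of
muscle/torque/reserve actuation. The heavy simulations in the test-suite and
the reproduction script run the torque-actuated variant (idealized joint
torques plus the small reserve actuators); the muscle layer is exercised by
its unit and property tests and by an assembly smoke test. With the default
MTU strengths the muscle-driven tracking of the synthetic trial is
capacity-limited (the trial's most violent swing transients exceed the
available muscle moments), which is reported by the solver as residual
infeasibility rather than hidden.

## Direct collocation

Optimal control problems are transcribed with flipped Legendre-Gauss-Radau
collocation: each of the N uniform mesh intervals carries third-order
Lagrange state polynomials through the interval start plus the three LGR
nodes (Radau IIA; right endpoint included), and piecewise-constant controls
parameterised at interval starts. Because the dynamics are posed in implicit
form (coordinate accelerations, muscle-state rates and ground reaction
forces are controls), the collocation equations are linear; the model
nonlinearity lives in algebraic path constraints enforced at interval
starts: the equation-of-motion residual, the GRF-consistency equality
(the GRF control equals the contact model's per-foot resultant), the Hill
equilibrium residuals and the activation rate inequalities. State continuity
between intervals is an explicit equality. Free-horizon problems are posed
on normalized time with the duration as an extra decision variable scaling
the dynamics and the quadrature. Lagrange costs are integrated with the LGR
weights; integrands are evaluated at the collocation nodes with the
interval's (constant) control. Variables are affinely scaled to [-1, 1]
from their bounds, and constraint rows by characteristic magnitudes.
Derivatives are exact: constraint Jacobians by vectorized complex-step
differentiation of the batched model evaluation, objective gradients and
Gauss-Newton Hessians from the cost-residual Jacobians.

### Solver

The transcribed NLP is solved by an in-package feasible-path
reduced-gradient SQP: a Gauss-Newton projection onto the constraint
manifold (sparse normal-equations steps), followed by descent steps
restricted to the constraint tangent space (projected conjugate gradients
on the Gauss-Newton model, truncated at an adaptive infinity-norm trust
radius) with a line search that re-projects every trial point; violated
inequality rows are handled by pinning them at their bounds (active set).
The motivation is the foot-ground contact law: its stiffness (~3.5e5 N/m at
running penetrations) makes linearized excursions of generic NLP methods
catastrophically infeasible, and off-the-shelf interior-point steps spend
their effort restoring feasibility far from the data. Keeping every iterate
feasible sidesteps this entirely; on tracking problems the method converges
in ~5-40 iterations from the spline initial guess. SciPy's `trust-constr`
interior-point method remains available through `solve(method="trust-constr")`.
The default convergence tolerance is 1e-3 on the reduced gradient
(tighter for the reproduction runs); non-convergence is reported through
the solution status, never an exception.

## Synthetic two-step experiments

The generator emulates the structure of an early-acceleration sprint trial
between the touchdown of one step (right foot) and the take-off of the next
(left foot): horizon 0.436 s, stance durations 0.185 s (right) and 0.165 s
(left), initial horizontal CoM velocity 4.5 m/s gaining 1.0 m/s over the
horizon, forward trunk lean, forefoot-strike contact with heel rise into
take-off, and touchdown 0.09 m ahead of the CoM; sampled at 250 Hz. These
defaults are the study conditions and are configurable.

Construction works backwards from the external forces so that dynamic
consistency is structural rather than approximate:

1. The whole-body CoM trajectory is prescribed: half-sine force pulses
   (the canonical spring-mass running profile, peaking ~2.2-2.3 BW) with an
   early-stance braking dip during stance, exact ballistic/drag-decelerated
   arcs in flight.
2. The stance-foot toe-sphere path is obtained by inverting the smooth
   contact law pointwise: penetration depth from the required normal force
   (with a few fixed-point sweeps for the dissipation term) and slip
   velocity from the regularized friction law. Contact is forefoot-only by
   construction; foot pitch follows a scripted roll profile.
3. Swing legs follow hip-relative polar profiles blended near the stance
   boundaries with a Taylor continuation of the absolute stance path
   (quintic weight over 50 ms), and internal angles come from planar
   two-link inverse kinematics with a smooth near-extension saturation.
4. The three unactuated floating-base rows of the equation of motion are
   then zeroed exactly by a coupled Newton boundary-value solve over a
   trunk-angle correction (the rotational absorber; pinned to zero at both
   ends since the forward problem is an unstable inverted pendulum) and
   pelvis translation corrections, with the CoM initial position/velocity
   as boundary conditions. Time derivatives are central differences on a
   2000 Hz grid with ghost nodes; the block-tridiagonal Jacobian is built
   by a 9-colored perturbation scheme.
5. Net joint moments are read off the internal rows of the equation-of-
   motion residual of the final trajectory; the worst base-row residual
   (typically < 0.05 N / N m, threshold 5) is stored as a diagnostic and
   generation fails if it is exceeded.

Determinism: all randomness (small waypoint jitter, optional measurement
noise) flows from the configured seed. Noise, when requested, is seeded
Gaussian on coordinates (and optionally GRF), to be removed by the
preprocessing filter.

Known limitations of the generated data: the post-take-off blend between
the stance path and the swing profile concentrates curvature into a ~50 ms
window, producing short joint-moment transients (a few kN m for ~10 ms)
just after take-off; they lie in flight, outside the detected stance
windows, so stance-based outcome measures are unaffected, but they inflate
whole-trial moment ranges. The heel spheres never load (forefoot-only
gait), and no soft tissue, marker artifact, or force-plate noise model is
included — passing the recovery tests therefore demonstrates correctness of
the pipeline on idealized data, not robustness to every artifact of real
laboratory trials.

## Data-tracking simulation

Raw measured inputs are low-pass filtered (zero-phase Butterworth,
effective fourth order, 20 Hz, with the dual-pass cutoff correction) and
the kinematics fitted with quintic B-splines providing coordinate
velocities and accelerations. Noise-free synthetic trials are splined
without re-filtering: they are already the product of a consistent
pipeline, and re-filtering them measurably breaks the relationship between
the kinematics and the stiff contact forces (phantom forces of ~0.1-0.2 BW
near take-off).

The objective is the weighted sum of squared normalized deviations —
coordinates, ground reaction forces, and net joint moments excluding the
MTP joints (tracking terms), activation effort weighted by maximal
isometric force (muscle runs), and control regularization (reserves,
coordinate accelerations, muscle-state rates) — with weights
w = [0.1, 0.05, 0.01, 0.01, 0.001, 0.0001, 0.1]. Tracked deviations and
the acceleration controls are normalized by 10% of each signal's range
(pelvis AP translation by 0.01 m so forward progression is matched
tightly); other controls by their bounds. Normalizers are floored
(0.01 rad/m, 5 N, 2 N m, 10 m/s^2) so a flat signal cannot produce a
near-singular weight. Bounds: kinematic states and accelerations extend
25% of each signal's range beyond its extrema (acceleration bounds are
additionally capped at 4x the 98th percentile so short-lived spikes in the
reference accelerations cannot destroy the variable scaling); reserves
+-10 N m (+-40 at MTP), GRF controls +-2500 N. Initial guess: states and
accelerations from the splines, actuator torques from the experimental
moments, reserves and GRF controls at zero. The horizon is fixed to the
trial duration.

## Predictive simulations

Each predictive problem starts from a solved tracking simulation and frees
the sagittal net moments named by its configuration (ankle/knee/hip,
single, pairs, or all three; both legs), tracking the remaining internal
moments against the tracking solution mapped onto normalized time
(stretch-to-fit when the horizon shrinks). The objective is
W1*tf + moment tracking + effort + controls with
W = [50, 0.1, 0.01, 1, 0.0001, 0.1]; moment deviations are normalized by
2% of each signal's tracking-solution range (floored at 0.5 N m). Boundary
constraints pin the initial multibody state and the terminal pelvis AP
displacement to the tracking values and keep terminal relative joint
angles within +-10 degrees of the tracking posture; the free horizon may
shrink by at most 5%. Bounds and all other machinery are identical to the
tracking problem; the initial guess is the tracking solution resampled on
the predictive mesh. MTP moments, when present, are part of the predictive
tracking set (maskable like any other internal moment).

## Outcome measures

Average horizontal external power is the change in horizontal CoM kinetic
energy divided by the elapsed time. Anterior-posterior impulses (net,
propulsive = positive part, braking = negative part) use trapezoidal
quadrature over each stance window; stance windows are maximal runs with
vertical GRF >= 20 N (touchdown = first crossing, take-off = last). The
touchdown variables are the horizontal velocity of the distal contact
sphere and its AP distance to the CoM (positive = foot ahead). Take-off
angles report hip extension, knee flexion, and thigh/trunk angles from the
global vertical (clockwise = extension/forward lean = negative); the
trunk-to-thigh angle is 180 + (thigh - trunk) degrees, above 180 the thigh
is in front of a line drawn parallel to the trunk (front-side mechanics),
below 180 behind it (back-side), with a +-1 degree neutral band. Peak net
joint moments are signed extrema within stance with their timing in
percent of stance (ties broken by the earliest occurrence); percentages
are rounded half-away-from-zero to one decimal.

## Problem sizes and numerical choices

The test-suite and the reproduction script run the reduced 10-DOF planar
model: tracking at N = 50 mesh intervals (order 3), the predictive suite at
N = 20-25 with a 25-iteration budget per run — sizes chosen so a single
desk CPU covers the full pipeline in minutes. Two discretization effects
of the reduced mesh are worth knowing: the piecewise-constant GRF controls
carry an approximation floor of ~0.05 BW per 8.7 ms interval on a 2.3 BW
half-sine (halved at N = 100), and sub-10 ms transients in the reference
accelerations cannot be matched exactly. The free-horizon predictive runs
typically drive the duration to its 5% lower bound on this synthetic trial;
with this weighting the time term dominates until the moment
tracking resists further compression.

Degenerate inputs: zero-range signals fall back to fixed normalizer floors
and unit bound margins; a model without contact spheres, muscles, or MTP
joints simply drops the corresponding constraint and cost blocks.
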