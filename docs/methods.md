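# Methods

This note records the model, the numerical procedures, the conventions
and the design choices behind `gaitscape`, in the package's own words.
Nothing here states an empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and assumptions

The walker is the powered "simplest walker": planar, point feet, rigid
massless legs, a point hip mass, and foot masses vanishingly small
relative to the hip.  Consequences used throughout:

- The stance leg is an unforced inverted pendulum, `θ̈ = sin θ`; the swing
  leg cannot load it.  The reduced step-start state `x = (θ, θ̇)` fully
  determines a step once the actuations are fixed, because the
  post-collision swing states are slaved to the stance states:
  `φ = 2θ`, `φ̇ = (1 − cos 2θ) θ̇`.
- Actuation is once per step: a push-off impulse `P ≥ 0` along the stance
  leg fired just before heel strike, and two hip-spring stiffnesses
  `k1` (active while φ > 0) and `k2` (φ ≤ 0).  The single-spring variant
  is `k1 = k2`.  Springs are allowed negative stiffness (a repelling hip
  torque); slow gaits require it.
- Heel strike is perfectly inelastic; the composite push-off + collision
  transition conserves angular momentum about the new contact point and
  never gains energy beyond the `P²/2` injected (asserted in tests).
- Walking direction convention: a step starts post-collision at
  `θ = +θ0` with `θ̇ < 0`, passes mid-stance, and ends at `θ = −θ0`;
  `φ` runs from `+2θ0` through zero (spring switch) to `−2θ0`.

Everything is dimensionless (mass / total mass M, length / leg length l,
time / √(l/g)).  `ScalingConstants` (defaults l = 1 m, g = 9.81 m/s²,
M = 1) converts step frequency to Hz via √(g/l) and step length to meters
via l.

## Integration and event handling

The swing phase is integrated by an adaptive Dormand–Prince 5(4) scheme
compiled with numba (`_kernel.py`), with mixed absolute/relative
tolerance 1e-13 by default.  A scipy DOP853 implementation with scipy's
own event machinery serves as an independent cross-check in the test
suite; the two agree on contact states to better than 1e-8.  The compiled
kernel exists because the perturbation-tolerance surveys execute on the
order of 10^5–10^6 event-detected step simulations; at ~0.2 ms per step
they take tens of seconds.

Events are detected by scanning each accepted step for sign changes,
bisecting a cubic Hermite interpolant, and polishing the event time with
Newton iterations that re-integrate tiny sub-steps, so event states carry
the full integration accuracy.  Four guards are active:

- **Contact**, the zero of `c = φ − 2θ`.  The contact function is zero at
  the step start by construction and the point foot also scuffs the
  ground at φ = 0 (mid-swing the foot legitimately passes below ground
  level — a standard artifact of point-foot models).  A crossing is
  accepted only with `φ < −1e-6` and a descending foot.
- **Spring switch** at φ = 0 (piecewise restart of the integration, so
  the stiffness discontinuity never degrades the error control).
- **Falls**: `|θ| ≥ π/2`, or the stance rate reversing sign before
  mid-stance (the walker rocks backward).  No contact before t = 50
  dimensionless time units is reported separately as `no_contact`.

A subtlety worth recording: at a periodic gait the contact surface and
the spring-switch surface cross zero *simultaneously* at mid-stance
(θ = 0 and φ = 0 at the same instant, by the time symmetry of the cycle).
Event masking after a fired event is therefore per-event-type; a shared
mask would swallow the genuine spring switch behind the rejected
mid-stance contact candidate, silently freezing the first spring for the
whole step.

## Limit cycles, continuation, and the canonical family

A gait solves the square system: periodicity of the reduced state (2
equations), achieved step length `2|sin θ_contact|` and step frequency
`1/T` equal to their targets, over unknowns `(θ, θ̇, P, k)`
(single-spring) or `(θ, θ̇, P, k1, k2)` with an appended symmetry
equation `k1 − k2 = 0` (double-spring; the modes agree at every sampled
gait and grids are swept in the cheaper parameterization).  The solver is
a damped Newton with forward-difference Jacobian and step halving;
convergence is `‖r‖∞ ≤ 1e-11`.  Candidates that fall or miss contact are
reported as residual-evaluation failures, distinct from numerical
stalling.  `P < 0` at a solution flags the gait instead of clamping it
(no such gait was observed on the solved space, consistent with the
push-off inequality never binding).

Grids are swept from the corner with the longest step and fastest
frequency, boustrophedon over the space, each cell warm-started from up
to eight nearest solved neighbors.  Cold solves use a deterministic
randomized multi-start around an inverted-pendulum estimate whose
stance-rate magnitude respects the mid-stance separatrix
(`θ̇² > 2(1 − cos θ0)` — a mean-speed estimate alone under-shoots at slow
gaits and every probe rocks backward).

**The solution surface is folded.**  Distinct stiffnesses can realize the
same fixed point and the same step time (the swing trajectory differs
mid-air while the stance trajectory, which is independent of the swing,
does not).  Which sheet a solve lands on depends on the continuation
path; one-dimensional homotopies can land off the sheet that the
neighbor-supported two-dimensional sweep selects.  The package therefore
*defines* the canonical gait at a specification as the one connected to a
module-cached reference sweep (0.05 increment over the full space), and
`solve_limit_cycle_continued` warm-starts every isolated solve from the
nearest node of that sweep.  Cold multi-start additionally rejects
solutions whose swing crosses φ = 0 more than once, which contradicts the
two-phase spring construction.  Only this single family is mapped; no
exhaustive multi-family search is attempted.

## Linearization

The discrete return map is linearized by one-sided forward differences
with probe size 1e-7 (central differences are available and used as a
cross-check): `A` from state probes, `B, D` from actuation probes, `C`
from the state probes' effect on the step outputs `(SL, SF)`.  Probe
sizes spanning 1e-8–1e-5 give consistent estimates, locating 1e-7 in the
linear regime above integration noise; individual finite-difference
entries carry a noise floor of roughly integration error / probe
≈ 1e-5.  Structural zeros hold to 1e-10: the push-off, applied at the
end of a step, cannot affect the next stance angle (`B[θ-row, P]`) nor
the executed step's outputs (`D[:, P]`).

Stability: a gait is open-loop stable when both eigenvalues of `A` are
inside the unit circle.  Region labels on an eigenvalue map are computed
by connected components of the stable mask (the largest is the center);
unstable cells are "left" or "right" of their row's stable band by step
frequency.  Controllability uses `rank [B, AB]` with a singular-value
ratio threshold of 1e-8.  The single-spring walker loses control on a
"zero-boundary" where `B[θ, k]`, `A[θ, θ̇]` and `B[θ̇, k]` vanish
together; `locate_zero_boundary` bisects the sign change of `B[θ, k]`
along a fixed-SL row.  Because the boundary entries sit at the
finite-difference noise floor, rank deficiency there manifests as the
singular-value ratio collapsing by two to three orders of magnitude
relative to off-boundary gaits rather than as an exact zero, and that is
what the tests assert.  The double-spring walker keeps a healthy ratio
(> 0.1) on the same gaits.

## Deadbeat control

The once-per-step law is `u_i = u_n − K (x_i − x_n)`, evaluated at the
state that starts the step it controls (springs set at the step's start;
the push-off, decided any time before the step's ending contact, from the
same state — fully causal and delay-free).  The closed loop is
`A − B K`; the deadbeat gain is the minimum-norm `K = B⁺ A`, which makes
`A − B K` vanish exactly when `B` has full row rank (the gain is
non-unique with three inputs and two states; the pseudoinverse choice is
deterministic and reproducible).  Negative push-off requests from the
linear law are clamped to zero.  Uncontrollable pairs raise rather than
synthesize garbage.

## Maximum tolerable perturbation

For a target gait, lattice neighbors (0.01 increment) are visited in
rings of increasing Euclidean radius in (SL, SF) space.  The walker
starts from the neighbor gait's limit-cycle state and must complete 100
steps without falling and return to the target (state within 1e-6,
max-norm) — under the target's deadbeat controller (controlled) or
holding the target's nominal actuations (open loop).  The MTP is the
largest radius whose enclosed neighbors all converge; the first failing
ring ends the search.  Protocol details the underlying description
leaves open, fixed here: lattice cells outside [0.1, 1.1]² are not gaits
and are skipped (edge targets are judged on their in-space neighbors);
the search is capped at radius 0.15; and a rollout may exit early once
its state error falls below 1e-10 *only* where the remaining steps are
provably repetitive (deadbeat-controlled, or open loop at an open-loop
stable target) — the map is deterministic, so a state that tight on the
fixed point replays the target cycle.

## Settling (response) time

The error series is the realized per-step value of the perturbed
quantity (SL or SF) minus its target, with the commanded perturbation as
the initial deviation.  Settling is counted from the *final* threshold
crossing (5% of the initial deviation; an error that dips below and
re-exceeds the threshold has not settled), refined to fractional steps by
linear interpolation between the bracketing steps.  Two counting
conventions coexist and both are always returned: counting from the
perturbed state as index zero (the `settling_time` utility's
convention), and counting the perturbed starting stride as stride one
(one larger).  The local-controller experiments report the latter; the
policy experiments the former.  The choice is a reporting convention,
not a dynamical one.

Local-controller experiments start the walker at the *perturbed gait's
own limit-cycle state* (solved fresh, warm-started from the target — MTP
radii are generally not lattice multiples, so reading the state off a
grid would interpolate) and run the target's controller for 40 steps.

## Gain-scheduled policy

Six gains, two nominal states and three nominal actuations per grid node
are interpolated bilinearly; queries on a node reproduce the stored
values bit-identically, and queries touching an unsolved cell or leaving
the hull raise.  Tracking interpolates the policy at the *next target*
on the path and evaluates the law at the current state, once per step,
stopping at falls.  RMS tracking errors are reported as a percentage of
the starting gait's SL and SF.

Response-time optimization commands the walker along two exponential
reference paths `target + (start − target)·e^{−s/τ}` (from gaits ±15%
along one axis, over at most 10 steps — 30 for the long-step/low-frequency
gait's frequency perturbation) sharing one time constant τ.  The cost
minimized over τ is the summed RMS deviation of the realized (SL, SF)
path from the *final target*, with falls penalized: commanding the
target too aggressively overshoots or falls, too slowly converges late,
so the optimum is interior.  (Costing the deviation from the reference
path itself is monotone in τ — a slower reference is always easier to
track — and drives τ to its bound with unbounded response time, so that
formulation is not usable as stated.)  The τ landscape has fall-penalty
plateaus; a deterministic coarse scan precedes bounded refinement.  For
frequency-axis perturbations the valley is flat over a range of τ, so
the resulting response times are sensitive to the exact cost
composition; length-axis results are robust.

Sinusoidal paths hold step length at twice the step-frequency rate with
equal amplitudes, `SL(s) = SL0 + a sin(4πs/n)`,
`SF(s) = SF0 + a sin(2πs/n)`, starting at zero phase.  The amplitude is
a free configuration parameter (default a = 0.1, a ±17% excursion at the
centre gait that stays inside the solvable space); minimum completable
path lengths depend on it, so they are reported per amplitude.  The
minimum-length search doubles n until a path completes, then bisects —
completion is not guaranteed monotone in n, so the result is the
smallest completing length found by that refinement.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so the
full suite completes in about a minute after kernel compilation: a 7×7
solved fixture patch (0.01 increment) for per-gait certificates; a 21×21
sweep of the full gait space (every 5th cell of the 0.01 grid) for the
eigenvalue-region means; its every-other-cell sub-sample (11×11, every
10th gait) for the MTP surveys; full-resolution 0.01 lattices for all
neighbor searches; and a 25×25 gain patch for the policy experiments.
The full 101×101 grid (10,201 gaits) is available through
`continuation_sweep` / `gaitscape solve-grid` and takes a few minutes on
one core.

## What the model does and does not show

All experiments run on the model's own synthetic dynamics; there is no
sensor noise, no actuator limit beyond `P ≥ 0`, full state feedback, and
perfectly rigid geometry.  Passing tests certify the mathematics of the
model and its controllers — existence and smoothness of the gait family,
the stability and controllability structure, one-step rejection of small
perturbations, multi-fold enlargement of tolerable perturbations, and
human-timescale convergence to commanded gaits.  They do not certify
behavior under state estimation error, compliant ground, 3D dynamics,
knees or a torso, within-step feedback, or any robot or human subject.
Known limitations inherited from the model class: the swing foot passes
below ground mid-swing (ignored, point feet); energy arguments treat the
hip point mass only; and the folded solution surface means statements
about "the" gait at a specification are statements about the canonical
family defined above.
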