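# Methods

`neurogait` simulates sagittal-plane human walking produced by a
reflex-driven neuromuscular controller, and studies what a feedforward
(CPG) component adds to it.  This note records the model, its
assumptions, the numerical choices, and the places where the design was
genuinely open.

## Musculoskeletal plant

The skeleton is seven rigid segments: a lumped trunk (head + arms +
torso) and, per leg, thigh, shank and foot, connected by six revolute
joints (hip, knee, ankle per side), all constrained to the sagittal
plane.  The hip point is rigidly fixed to the trunk (no pelvis motion)
and the foot has no toe segment.  Generalized coordinates are the hip
position, the trunk angle and six relative joint rotations (9 DoF).
Default anthropometrics are Winter-style values for an ~80 kg, 1.80 m
model (trunk 53.5 kg, thigh 8.5, shank 3.5, foot 1.25 per side); every
value is overridable.

Dynamics are Lagrangian: the mass matrix is assembled from center-of-mass
Jacobians, the velocity-product (Coriolis/centrifugal) term uses the
exact analytic time derivative of those Jacobians, and gravity, contact,
muscle/ligament torques and external pushes enter as generalized forces.
The equations of motion are advanced with classical RK4 at the 1 ms
control step.  On passive conservative configurations this integrator
conserves mechanical energy to ~1e-14 relative over one second (tested),
and free-flight center-of-mass motion is ballistic to integrator order.

**Joint soft limits.**  Ligaments are a nonlinear spring–damper engaging
beyond a joint's angular range:

    tau = k * dphi * (1 + omega/omega_ref)   if dphi > 0 and omega/omega_ref > -1
    tau = 0                                   otherwise

with k = 17.19 N·m/rad, omega_ref = 1.74e-2 rad/s, dphi the over-travel
and omega the angular rate oriented positive toward/past the limit.  The
torque is exactly zero inside the range and when the joint retracts
faster than the reference speed, and is continuous at dphi = 0.  Default
ranges: hip 110–220°, knee 45–180°, ankle 60–130° (interior angles;
180° = straight limb, standing ankle = 90°).  The knee's upper limit sits
at the straight leg so quiet standing generates no ligament torque.

**Ground contact.**  The same spring–damper family models the ground:
vertical force `k_z * depth * (1 + v_pen/v_ref)` clamped at zero (the
ground pushes, never pulls), plus a horizontal stiction spring saturated
by a sliding-friction cone |f_x| <= mu f_y.  Defaults (k_z = 8e4 N/m,
v_ref = 0.5 m/s, k_x = 8e3 N/m, d_x = 300 N·s/m, mu = 0.9) were chosen
once for stable 1 ms RK4 integration of an ~80 kg model; the original
study delegated contact to a physics engine whose constants are unknown,
so force traces are comparable to published ones only qualitatively.
Terrain is a piecewise-linear elevation profile; the randomized
environment generator produces trapezoidal up/down structures with every
gradient at or below 5%, with lengths, slopes and spacings drawn from a
seeded generator.

Falls are declared when the trunk COM drops below 70% of its standing
height above the local ground or the trunk pitches beyond 60°; the
episode then terminates with a flag.  The original criterion is not
published; this one is the package's own.

## Muscle–tendon units

Each leg carries seven Hill-type MTUs (GLU, HF, VAS, SOL, TA, HAM, GAS;
HAM and GAS are bi-articular).  The contractile element (CE) force is

    F_CE = F_max * f_l(l_CE) * f_v(v_CE) * A,

with the bell force–length `f_l = exp(c |(l - l_opt)/(l_opt w)|^3)`
(w = 0.56, c = ln 0.05), a hyperbolic concentric force–velocity branch
vanishing at the maximal shortening velocity and an eccentric branch
saturating near N = 1.5 (K = 5); `f_l(l_opt) = 1`, `f_v(0) = 1`.  The
tendon (SE) is quadratic over a strain tolerance eps_ref = 0.04, and two
quadratic buffers (PE above l_opt, BE below l_opt(1 - w)) keep the fiber
in range.  The net force is `F_m = F_SE = F_CE + F_PE - F_BE`, never
negative at the tendon.  Sign convention: v_CE > 0 is lengthening.

The CE velocity comes from the CE/SE force equilibrium: the tendon force
at the current geometry fixes the required f_v, which is inverted in
closed form; targets beyond the eccentric asymptote clamp the velocity
at ±v_max.  l_CE is advanced by 20 explicit Euler sub-steps per 1 ms
control step (a refinement test shows 20 sub-steps at 1 ms match single
sub-steps at 0.05 ms to 1e-6 relative).  Activation follows
`dA/dt = tau_A (X_mtu - A)` with tau_A = 100 1/s, integrated with the
exact exponential update and clamped to [0, 1].

**Geometry.**  Moment arms are constant (r_0) at the hip and
`r_0 cos(phi - phi_max)` at knee and ankle, with r_0, phi_max and the
reference angles phi_ref from the model's joint table (e.g. GLU hip
r_0 = 0.10 m, HAM 0.08 m at both hip and knee).  MTU length is
normalized so that `l_mtu = l_opt + l_slack` with every attached joint
at its reference angle.  The fiber-length excursion is attenuated by a
pennation-like factor rho (0.5–0.7 per attachment, the convention of the
underlying published muscle model) while torque acts at the full
anatomical arm; with rho = 1 the length gradient equals the moment arm
exactly (virtual work), and the test suite pins that property in the
rho = 1 configuration.  F_max, l_opt, l_slack and v_max are not printed
in the source study; the shipped defaults are the standard values of the
reflex-walking literature and are flagged as inherited constants.

## Reflex network

Walking is generated by 15 delayed feedback pathways per limb (the
published pathway table): six muscle-force (Golgi, type 1b) and three
muscle-length (spindle, type 1a) pathways — nine muscle-sensor pathways
per limb — plus load-weighted PD balance pathways from trunk pitch onto
GLU/HAM/HF during stance, a contralateral-load inhibition of VAS during
double support, a swing-phase trunk-lean drive of HF, and a knee
overextension-prevention inhibition of VAS.  Each stage is an affine map
followed by a clamp to [0, 1]; interneuron polarities follow the table's
signs (inhibitory pathways subtract at the motoneuron).  Muscle
stimulations are clamped to [0.01, 1]; the 0.01 floor models muscle
tone.

Sensor signals are normalized (forces by F_max, lengths by l_opt, foot
loads by body weight).  Transmission delays are 2.5 ms (hip muscles,
trunk), 5 ms (knee level) and 10 ms (ankle level, ground sensors),
applied twice per loop — sensor to interneuron and motoneuron to muscle
— with no interneuron-to-motoneuron delay.  On the 1 ms grid the 2.5 ms
delay rounds up to 3 steps; delay lines are exact shifts for whole-step
delays and are pre-filled with the first sample.

**Gait state machine.**  A limb with normalized load below 0.1 is in
swing (SW).  A loaded limb whose contralateral limb has just touched
down enters finishing stance (STend) and remains there until its own
takeoff; otherwise it is in stance (ST).  (The printed STend condition
"GRF <= 0.1" contradicts the swing rule; a limb in finishing stance must
be loaded, so the rule is implemented with the limb loaded.)  Stance
pathways are gated on {ST, STend}, stance-end pathways on STend only,
swing pathways on SW, cycle pathways always.  During flight both limbs
are SW and each limb's gates resolve by its own state.  The balance PD
value is the positive part of `kp (pitch - theta_ref) + kd pitch_rate`,
weighted by the ipsilateral foot load; it excites the extensors and
inhibits HF, so an unloaded limb receives no correction.

The layered network (sensors → interneurons → motoneurons → muscles) is
functionally identical to a direct delayed sensor→muscle map when the
total loop delay matches; a test pins this equivalence.

## Feedforward (CPG) extension

The CPG layer treats each muscle-sensor pathway's predictor as a model
of its interneuron signal and blends the two per pathway:

    X_mn = G^s (alpha * X_in_sen + (1 - alpha) * X_in_cpg) + X0_mn,

algebraically identical to the feedforward-plus-corrective form
`G^s (X_cpg + alpha (X_sen - X_cpg)) + X0` (tested to machine
precision).  alpha = 1 everywhere reproduces the pure-feedback model
bitwise (tested at the full-engine level); alpha = 0 is purely
feedforward.

Two predictor families: the **constant predictor** (mean of the signal
over its active phase window) and the **morphed oscillator**

    theta' = omega,
    x'     = gamma (g(theta) - x) + dg/dtheta * theta' + K,

with gamma = 100 (offset from the limit cycle decays as exp(-gamma t);
tested), K = 0 by default (the source never defines K; synchronization
is handled by the event coupling, and K remains a config hook).  The
shaping function g is a periodic cubic spline through the pointwise mean
of time-normalized signal cycles, cut at the ipsilateral takeoff for
swing pathways and touchdown otherwise; mean samples are clamped to
[0, 1] before fitting and g(0) = g(1) by construction.

Four phase clocks drive the predictors (left/right ×
touchdown-/takeoff-synchronized); stance- and cycle-phase pathways bind
to the touchdown clock, swing pathways to the takeoff clock.  All clocks
share one frequency omega, initialized from the recording's mean cycle
rate.  Between events the phase follows omega until a fraction p = 0.9
of the nominal period, then the slowing-down rate

    c(t) = omega * exp(-(omega/(1-p)) (t - p/omega)),

which is continuous at the onset (c(p/omega) = omega) and whose
remaining integral is exactly 1 - p, so theta < 1 strictly before the
event (equality only at float rounding after very long waits; the
implementation advances theta with the closed form, not quadrature, so
the bound is structural).  Every synchronization event restarts the
phase at 0 — for a lagging oscillator (t > 1/omega at the event) this is
the formal reset rule; for a fast oscillator the slowdown has already
parked theta at ~1 ≡ 0, so the restart is continuous.  The oscillator
output state x is not reset, it re-converges at rate gamma.

Two supraspinal commands modulate the network: omega (shared by all
four clocks) and amplitude scalings mu_osc / mu_cst applied to the
predictor outputs before combination (outputs are re-clamped at the
motoneuron).  Five named alpha-map presets encode the published model
variants (ankle, hipA, hipB, biArt, min_fdb) from their textual
descriptions — the exact published alpha maps exist only as a figure, so
the preset values are documented configuration, not ground truth.  The
min_fdb preset reproduces the 35% muscle-feedback activity figure; the
companion all-pathway figure (45%) would require partially replacing
balance pathways, which the preset does not do by default.

## Episode engine

Per 1 ms step: read raw sensors → push through delay lines →
interneurons → (optional CPG blend) → motoneurons → delay → stimulation
clamp → 20 muscle sub-steps → muscle + ligament torques → contact →
RK4 plant step → state machine update → log.  Episodes are bitwise
deterministic given (config, seed): the engine draws no random numbers;
randomness enters only through the seeded environment generator.
Initial condition: upright stance with a small forward COM velocity
(default 1.2 m/s), legs slightly split, slight forward lean, feet placed
at the static equilibrium penetration of the contact springs.  External
pushes are horizontal forces on the trunk COM over a 0.25 s window
(configurable); push robustness is measured by monotone bisection (1 N
resolution) on the largest force survived.  Offline event detection uses
threshold crossings of the 0.1 load level with a 20 ms debounce window
(below physiological double-support durations, suppressing contact
chatter).

## Optimization

The controller has 25 open parameters shared between the mirrored
limbs: 7 basal motoneuron activities, the trunk reference pitch, 3
muscle-length feedback offsets and 14 reflex gains (6 force, 3 length,
balance kp/kd, contralateral-load, trunk-lean and knee-overextension
gains).  They are optimized by a particle swarm with lexicographic
staging: (1) maximize distance until d_lim = 20 m is covered, (2) hold
|v - 1.3| <= 0.05 m/s, (3) minimize the knee-overextension penalty (the
time integral of knee ligament torque magnitude) below 10 N·m·s,
(4) minimize metabolic energy.  A candidate's score is the tuple (stage
reached, stage fitness); higher stage always wins, ties break by the
stage's objective.  Candidate evaluation runs five independently seeded
slope environments and keeps the lexicographically worst tuple.  PSO
hyperparameters are the canonical constriction settings (inertia 0.729,
cognitive = social = 1.494, velocity clamp at 20% of range, reflecting
walls); the source publishes none.  Stage thresholds and parameter
ranges live in an unpublished supplement; the shipped manifest values
are the package's own documented choices.

Metabolic energy uses a Bhargava-style decomposition: per-muscle mass
from F_max and l_opt (specific tension 0.25 MPa, density 1059.7 kg/m³),
activation/maintenance heat proportional to mass and activation,
shortening heat, and positive CE work; a cheap fallback (time integral
of summed squared stimulations) is selectable for fast staged searches.
Constants are package defaults, not fitted values.

The shipped reference parameter vector
(`src/neurogait/_reference/reference_params.json`) comes from a
deliberately scaled-down in-repo search (seeded PSO, short flat-ground
episodes; script `scripts/find_reference_gait.py`).  It produces a gait
that walks for seconds, not indefinitely — reproducing the published
walking solutions requires optimization campaigns orders of magnitude
larger — so integration tests assert episode mechanics (determinism,
clamps, equivalences, event logic) rather than gait quality.

## Analytics

* **Cost of transport**: CoT = E/(m d).
* **Gait harmony**: per cycle, GR0 = cycle/stance, GR1 = stance/swing,
  GR2 = swing/double-support, averaged over cycles.  Double support is
  the *total* both-feet-loaded time per cycle, which makes all three
  ratios equal the golden ratio at a duty factor of exactly 1/phi
  (closed form, tested); GR2 is flagged undefined without double
  support, and cycles whose start precedes the contralateral record are
  excluded from the GR2 average.
* **Cycle-normalized correlation**: strides cut at events, spline-
  resampled to 1000 points, averaged, Pearson-correlated with a
  reference cycle; constant signals are flagged (nan).
* **Feedback activity**: 100 * mean(alpha).
* **Feedback sensitivity**: per pathway, beta = 1 - alpha swept over
  0, 0.1, ..., 1.0 with an oscillator predictor and all other pathways
  pure feedback; the sensitivity is 1 minus the largest stable beta
  (0 = fully replaceable).  The scan takes an injectable stability
  callback so its logic is testable without a long-lived gait.
* **Supraspinal grid scan**: 11 × 11 cells over omega in [0.2, 2.5] and
  mu in [0.1, 4.0]; cells are classified stable / asymmetric / unstable
  (no fall and cycle-duration CV < 5%; stride-length L/R difference
  > 5% flags asymmetry — the published gray-cell criteria are unstated,
  these are the package's own) and unstable cells carry no speed value.
* **Passive predictor quality**: shaping functions extracted from the
  first 40 of 50 synthetic cycles, oscillators run passively on the
  held-out cycles synchronized only by the event trains (with a
  two-cycle burn-in so every clock has synced before scoring), scored by
  per-pathway Pearson correlation.

## Synthetic substrates

The synthetic gait generator emulates the *statistics* of steady
symmetric walking that the predictor pipeline consumes: per-pathway
smooth periodic bursts inside the correct phase windows, per-cycle
Gaussian period jitter (default 2%) and amplitude noise (default 2%),
consistent touchdown/takeoff trains, the right limb phase-shifted by
half a cycle, all reproducible from a seed.  It does **not** emulate
closed-loop dynamics: no sensor-to-motion coupling, no asymmetries, no
perturbation responses.  Passing predictor tests on it therefore show
the extraction/oscillator machinery is correct under controlled
variability — not that predictors reproduce real feedback signals of
this plant, which requires a stable optimized gait.

Single-muscle rigs (isometric, passive stretch, quick release) isolate
the MTU dynamics for regression tests; all fixtures run in well under a
second.

## Known limitations

* No published gain set: the shipped defaults and the desk-scale
  reference vector do not walk indefinitely; headline gait-level numbers
  (CoT range, push robustness 40→28 N, speed transitions) are
  qualitative references only.
* Contact constants are free defaults; absolute GRF traces are not
  comparable to engine-based published traces.
* 2.5 ms delays round to 3 ms on the 1 ms grid.
* The balance-pathway PD structure is parameterized (the published gain
  structure is not printed) and left to the optimizer.
* Vertical-only penetration depth in contact (adequate for gradients
  <= 5%).
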