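# Methods

This note documents the models implemented in `reachgen`, their
assumptions, the parameter defaults and why they were chosen, and the
design decisions taken where the procedure was genuinely open.

## Arm model and coordinate conventions

The arm is a planar chain of three rigid segments — upper arm, forearm,
hand — with default lengths 0.30, 0.25 and 0.07 m (an average adult arm).
Joint angles are *relative*: each is measured against the previous
segment's orientation, with the base axis along +x of the workspace frame.
The hand's orientation in external space is therefore q_s + q_e + q_w, and
holding it constant is the linear constraint q̇_s + q̇_e + q̇_w = 0.  The
training posture is shoulder 35°, elbow 75°, wrist 12.3° (the group-mean
wrist angle; subject-specific values can be passed anywhere a posture is
accepted).  All internal units are SI.

Three Jacobian variants are provided: the full 2×3 three-joint map, a 2×2
map with the wrist treated as a fixed joint, and a 2×2 map in which
forearm and hand act as a single "virtual" segment from elbow to hand
(length √(l₂² + l₃² + 2 l₂ l₃ cos q_w)).  Two-joint postures whose
Jacobian determinant falls below 1e-9 (straight or folded arm) trigger a
warning or, where an inverse is required, an error naming the posture.

## Fields

The training perturbation is the viscous field F = B ẋ with
B = [[−10.1, −11.2], [−11.2, 11.1]] N·s/m.  B is symmetric with one
stable and one unstable eigendirection — not a curl field — so different
movement directions feel genuinely different forces.  Its joint-space
analog is W = J_trainᵀ B J_train; rendering that map back at the hand,
F = (Jᵀ)⁻¹ W q̇ with J evaluated at the current posture, defines the
intrinsic field.  The two renderings coincide exactly at the training
posture and pull apart as the posture changes; in the translated testing
workspace of the workspace-transfer protocol they are close to orthogonal.
W for that protocol is built from the Jacobian at the center of the
training workspace (the evaluation point is configurable; the original
apparatus' choice is not recorded).  That protocol uses a two-joint arm
with the hand folded into the forearm (links 0.30 and 0.32 m).

The mechanical channel is a one-dimensional spring-damper wall (5000 N/m,
2 N·s/m) perpendicular to the start→target line.  The damping unit is
taken as N·s/m — the dimensionally consistent reading for a damper.

## Generalization predictions

The test battery crosses three joint configurations — (35°, 75°),
(35°, 120°), (80°, 75°) — with five hand orientations (wrist offsets 0 to
−45° in 11.25° steps): 15 postures, each probed by one 10-cm channel
movement planned as a minimum-jerk reach of 0.4 s sampled at 1 kHz.
Within a configuration, the five orientations share the wrist-joint
position and translation exactly.  Configuration 1 moves directly ahead.
The shared direction of configurations 2 and 3 is not part of the recorded
protocol; the default, 67.5° counterclockwise of straight ahead
(forward-left), was chosen because it makes the Cartesian prediction
strongly negative at those configurations, the joint-based prediction
small at configuration 3, and the object-based prediction monotone in
wrist angle — the qualitative pattern the paradigm is designed to expose.
It is a config parameter, as is every direction.

Model predictions:

* **Cartesian (C)**: F(t) = B ẋ(t), independent of posture.
* **Object-centered (O)**: F(t) = R(θ) B R(θ)⁻¹ ẋ(t), where θ is the
  change in *hand orientation in external space* between test and training
  postures (not the wrist angle — shoulder and elbow rotations move the
  tool frame too).
* **Joint-based (J)**: F(t) = (J Jᵀ)⁻¹ J W q̇(t).  Joint velocities come
  from the constant-orientation constraint; the test Jacobian is
  re-evaluated every millisecond while the posture is integrated along the
  movement.  By default the training-side map W(t) likewise follows a
  matched execution of the same velocity profile at the training posture.
  This choice makes the prediction collapse to F = B ẋ *exactly* when the
  test posture is the training posture — the identity that anchors the
  normalization — which a W frozen at the training posture's start cannot
  do, because joint angles change by tens of degrees over a 10-cm reach
  this close to full extension.  `track_training=False` recovers the
  frozen-W variant; the two differ by a few percent of the training
  magnitude across the battery.  The 2×2 variants (fixed wrist, virtual
  segment) use F(t) = (J_testᵀ)⁻¹ J_trainᵀ B J_train J_test⁻¹ ẋ(t) and
  produce very similar patterns (correlation > 0.95 across the 15
  movements); the three-joint model is the default for fitting.

Each predicted force series is projected onto the channel normal (the left
normal of the movement direction, which rotates with the movement),
averaged over 50–450 ms after movement onset (speed first exceeding
0.5 cm/s), baseline-subtracted when a preexposure series is supplied, and
divided by the model's own signed training-posture magnitude.  Every model
is therefore exactly 1 at the training movement.  Plans are padded with
200 ms of rest so the window is always covered.

## Mixture and decay fits

The fitting target is the concatenation of all subjects' per-movement
normalized adaptation values (9 × 15 = 135 points at full size).  The
mixture model is

a(m) = k_j J(m) e^(−d_j Δθ²) + k_c C(m) e^(−d_c Δx²) + k_o O(m) e^(−d_o Δθ_hand²)

with Δθ² = Δθ_s² + Δθ_e² + Δθ_w² (rad²), Δx² the squared Cartesian hand
displacement (m²), and Δθ_hand² the squared hand-orientation change
(rad²), all measured between the test start posture and the training
posture.  Weights are constrained nonnegative and summing to 1 — the
model then accounts fully for learning at the training posture — and
decay rates are nonnegative.  Degrees of freedom: p−1 for a p-component
mixture without decay (0/1/2), plus one rate per component with decay
(1/3/5); the no-generalization reference (prediction ≡ 0 everywhere) has
0.

Optimization is SLSQP with the explicit simplex constraint and bounds,
from 10 seeded random restarts (Dirichlet weights; decay rates log-uniform
over 10⁻² – 10³, covering the rad⁻² and m⁻² scales).  Decay models are
non-convex in d, hence the restarts; no-decay models are convex quadratic
programs for which any start reaches the optimum.  Convergence tolerance
is 1e-12 on the MSE; the best converged restart wins, and a fit in which
no restart converged is flagged in the result.  Tests cross-check the
optimizer against an exhaustive 0.01-resolution simplex grid.

Model comparison uses BIC = n·ln(MSE) + k·ln(n) (lower better); ΔBIC/2
approximates a log Bayes factor.  Ties break toward fewer degrees of
freedom, then lexicographic component order.  Leave-one-subject-out
cross-validation fits each model to the across-remaining-subjects average
per movement and scores the held-out subject by variance explained
1 − SSE/SST, which goes negative when the model predicts worse than the
subject's own mean.  Subjects are equally weighted by fitting per-subject
movement means; handling of missing trials is the caller's concern.

## Synthetic data

The generator reproduces the two study protocols at their printed sizes.

*Generalization protocol*: preexposure 128 trials (113 null walk movements
+ 15 channel probes, one per test movement), exposure 496 field movements,
generalization 600 trials (525 field + 75 channel probes, 5 × 15, each
probe immediately followed by a field movement).  Walk targets are 10-cm
reaches in 8 directions forming a pseudorandom walk inside the 15 × 15 cm
training square; infeasible directions are resampled, and channel probes
are placed by a gap construction that guarantees non-adjacency.

*Workspace-transfer protocol*: two 250-trial baseline blocks (training
then testing workspace, 48 random no-vision trials each), 2 × 500
adaptation trials with 192 random no-vision trials of which exactly half
are null-field catch trials, then 80 all-no-vision generalization trials
formed as randomized center-out pairs balanced at 10 reaches per
direction, with field assignment per subgroup (40/40
extrinsic/intrinsic, or 27/27/26 with null).  The extended-exposure
variant adds a third 500-trial block; its no-vision count (288) keeps the
printed rate, which is not itself recorded for that variant.  The
no-arm-vision variant changes no counts.  Geometry: shoulder 15 cm left
and 40 cm in front of the workspace center, translated 30 cm further left
for testing.

Channel-trial datasets are drawn as
subject_scale × mixture(m) + N(0, σ), with σ expressed as a fraction of
the training-posture magnitude (default 0.1, the scale of between-trial
variability in trained subjects) and subject scales N(1, 0) by default.

Simulated reaches use a point-mass hand (2 kg) tracking the minimum-jerk
plan with spring-damper feedback (2 kN/m, 40 N·s/m) plus a learned
feedforward compensation equal to the adaptation fraction times the ideal
opposing force; on catch trials the field is off but the feedforward
remains, producing the mirror-image aftereffect.  Learning follows a
single-rate exponential toward an 0.8 asymptote (channel forces plateau
near 80% of full compensation in trained subjects) at 0.01 per field
trial.  None of this is a biomechanical claim: the learner and controller
exist to produce qualitatively correct learning curves and aftereffects,
and the generator reproduces neither muscle dynamics, visual feedback, nor
the idiosyncratic variance structure of real subjects — passing tests on
synthetic cohorts demonstrate the correctness of the *analysis*, not the
behavior of humans.  Cohort simulations sample every 10th exposure trial
at a 5-ms step to keep full-protocol runs inexpensive; schedules and
datasets are always generated at full size.

## The ρ statistic

ρ compares a trial's velocity trace to the direction-matched average
baseline trace, both aligned to the 0.1 m/s onset crossing, over a window
from 125 ms before to 750 ms after alignment.  The corrected formula from
the literature is not reproduced in the primary description, so `reachgen`
operationalizes it as the mean over 100-ms sliding windows of the inner
product ⟨v_trial · v_baseline⟩, divided by the identical statistic of the
baseline with itself — rho(baseline, baseline) = 1 by construction, 0 for
orthogonal velocities.  The window length and data window are config
parameters, and the normalization choice is the main caveat when comparing
absolute ρ values to published ones.  Velocities are estimated by central
differences followed by a 3rd-order 20-Hz low-pass Butterworth filter.

## Known limitations

* The exact test-movement directions for configurations 2 and 3, and the
  channel-normal sign convention of the original apparatus, are not
  recorded; the defaults reproduce the designed qualitative contrasts but
  individual signed values at those configurations depend on the choice.
* The decay distances use the movement *start* posture; a path-averaged
  metric would differ slightly for the larger postural excursions.
* BIC here assumes i.i.d. Gaussian residuals across concatenated points;
  subject-level correlation is ignored, exactly as in the standard
  analysis this package implements.
* The reach simulator is phenomenological (see above).
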