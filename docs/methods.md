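# Methods

`palpsim` simulates, end to end, a tele-palpation apparatus in which an
operator drives a remote indenting stage by hand gestures, receives the
measured contact force as a neuromorphic spike train, and declares buried
stiff nodules by key press. This note records the model, its assumptions,
the tunable parameters that matter, and the design decisions taken where the
apparatus admitted more than one reasonable realization.

## Phantom and contact model

The phantom is a 100 × 100 × 15 mm cuboid of soft silicone containing
hemispherical inclusions of 5 mm radius; by default 3 replicas each of four
stiffer polymers are placed uniformly at random (rejection sampling, 5 mm
edge margin beyond the inclusion radius, pairwise center distance greater
than the sum of radii, hard cap of 10 000 draws per inclusion). Each
material is reduced to a single **vertical stiffness** k = ΔF<sub>z</sub>/Δz
(N·mm⁻¹): matrix 2.14; inclusions 2.74, 2.88, 3.68, 3.69. Contact is
linear-elastic, F = k·z — no Hertzian or finite-element mechanics, no
viscoelasticity, no shear. Burial depth is not modeled mechanically: the
inclusion's surface footprint disk carries its measured stiffness directly,
because a per-site ΔF<sub>z</sub>/Δz is exactly what an indentation
characterization measures. At the footprint margin the field is a hard step
by default (`blend_width = 0`, boundary belonging to the inclusion); an
optional linear blend band makes it continuous, since nothing constrains how
stiffness varies at the margin of a buried hemisphere.

The characterization protocol indents a site at 0.125 mm·s⁻¹ until
F<sub>z</sub> ≥ 0.5 N, optionally adding Gaussian load-cell noise (default
SD 0.01 N, a realistic figure for a six-axis load cell at these loads), and
estimates k as the ordinary least-squares slope of force on depth, pooling
5 trials by median/IQR/range. On noiseless series this recovers the
generating slope to machine precision; bias vanishes with the noise.

## Gesture control

Stage velocity is a dead-zone proportional law: zero while the hand stays
within ρ₀ = 50 mm of the sensor center, otherwise directed along the
horizontal projection of the hand displacement with magnitude
min(g·(ρ − ρ₀), v_max). The proportionality gain g (default 1 mm·s⁻¹ per
mm) and the clamp v_max (default 20 mm·s⁻¹) are free parameters of the
apparatus; the clamp exists because an unbounded proportional law would let
a fully extended arm command speeds the stage could not track. ρ = ρ₀
belongs to the dead zone, making speed continuous at the boundary. Only
X–Y motion is gesture-driven; the vertical axis is governed by the force
servo below. Invalid hand samples are held at the last valid value.

Tracking error is the area metric used for apparatus characterization: a
compact boundary is extracted around the executed planar path (convex hull
at `boundary_shrink = 0`, increasingly concave via `shapely.concave_hull`
as the parameter approaches 1; default 0.5) and its shoelace area is
compared with the target's: error rate = 100·|A_tracked − A_target|/A_target.
At 720 samples an ideal circle of radius 30 mm scores 2827.3 mm² (inscribed
720-gon), within 0.5 % of πr² = 2827.43 mm².

## Neuromorphic encoder

The force-to-spike transducer is a regular-spiking Izhikevich neuron
(a = 0.02, b = 0.2, c = −65, d = 8, peak 30 mV — the canonical
regular-spiking set) Euler-integrated at 5 kHz (dt = 0.2 ms), driven by
I(t) = offset + gain·F(t) with offset 0 by default (no spontaneous rate).
A spike is a threshold crossing v ≥ 30 mV detected after the Euler update
and stamped at the end of that step; divergence of the integration is
detected before the reset so an overflow cannot masquerade as a spike.

Calibration counteracts rate saturation: the simulated f–I curve (1 s
measurement after a 0.5 s settle, on an integer current grid up to 60) is
truncated at its first rate decrease, and the gain is chosen by inverse
interpolation so that F = 0.5 N lands on the current firing at the top of
the target rate range (default 100 Hz, a typical sustained mechanoreceptor
afferent rate and comfortably inside the monotone region — the calibrated
gain is 94 current units per newton). At dt = 0.2 ms the spike count over
1 s of constant input stays within 5 % of a dt = 0.01 ms reference
integration across the calibrated range; the residual deviation is
dominated by count quantization at the low-force end.

Each spike drives the actuator with one biphasic square pulse (default
width 1 ms) of ±100 V about the 105 V baseline — peak-to-peak 200 V,
matching the driver's electrical settings; overlapping pulses are summed
and clipped to the driver's excursion. Pulse shape is a modeling choice;
only amplitude, offset and gain are constrained by the electronics.

## Session loop, force servo and latency

One session runs at the control rate (default 100 Hz; gesture sensors
operate near this) for a default 360 s. Per step: hand sample → velocity →
stage Euler step clamped to the workspace → local stiffness lookup →
vertical servo → logging. The force stream is passed through the latency
channel, resampled to 5 kHz, encoded to spikes, and handed to the virtual
subject. All sub-streams (latency jitter, subject scatter) derive from one
session seed via named `SeedSequence` spawns, so identical configuration +
seed reproduce byte-identical logs.

**Force servo.** The platform's protective 0.5 N threshold is a hard clamp
on F<sub>z</sub>, asserted on every simulated log. Between clamp events the
probe depth follows a first-order servo toward a force setpoint:
ż ∝ (F_set/k − z)/τ. Two parameters were genuinely open and were fixed by
the physics of the feedback itself:

* **setpoint 0.25 N** — half the protection threshold. Crossing from matrix
  (k = 2.14) into the stiffest inclusion (k = 3.69) at constant depth
  multiplies the force by k_inc/k_mat ≤ 1.72, so any setpoint above
  0.5/1.72 ≈ 0.29 N drives the entry transient of *every* material into the
  clamp, erasing the stiffness differences the feedback is supposed to
  convey. At 0.25 N the transient peaks range from 0.32 N (softest
  inclusion) to 0.43 N (stiffest), all below the clamp and ordered by
  stiffness.
* **servo time constant τ = 0.4 s** — the timescale on which a person
  re-regulates grip/contact force. A much faster servo (tens of ms) returns
  the force to the setpoint before a rate estimate over any plausible
  perceptual integration window can register the change, leaving the
  subject blind by construction.

**Latency.** Transport is simulated, not networked. The channel re-reads
the force signal at t − d(t), with d fixed (ILS: platform in line of sight,
local) or uniformly jittered in [0, bound] (NILS: remote), bound 15 ms —
the transport's guaranteed maximum. The channel is causal and
order-preserving; with bound 0 the ILS and NILS modes produce identical
logs for the same seed, so any ILS/NILS difference is attributable to
latency alone.

**Trajectories.** Scripted hand sources invert the control law: from a
desired stage path the required velocity, hence the hand displacement
ρ₀ + |v|/g along it, is computed per step. The default exploration is a
serpentine raster with 10 mm line pitch at 10 mm·s⁻¹ — linear paths are
both the natural palpation strategy and the best-tracked geometry — which
passes within 5 mm of every point of the block, guaranteeing every
inclusion is overflown.

## Virtual subject

Humans performed the original task; the virtual subject is a deliberately
simple stand-in with every parameter exposed. The detector estimates the
spike rate in a sliding window (0.25 s, hop = window/4), compares it with a
running baseline (median of the previous 5 windows), and presses when the
departure exceeds 12 Hz, then is refractory for 1 s; presses are delayed by
a 0.3 s reaction latency and their recorded position scattered
isotropically (SD 2 mm). The window and threshold are matched to the servo
transients above: a 0.25 s window integrates most of a τ = 0.4 s transient,
and 12 Hz sits between the window-averaged rate excursions produced by the
softer inclusion materials (roughly 10–13 Hz at the calibrated ≈200 Hz·N⁻¹
rate gain) and the stiffer ones (roughly 25–30 Hz), which is what makes
identification stiffness-graded rather than all-or-none.

Separately, `psychometric_response` draws detections directly from
P = γ + (1 − γ − λ)·G(x) with G the logistic CDF — the generative model the
fitting routine assumes. Parameter-recovery tests use this generator, not
the detector, so they validate the fit without entangling it with detector
heuristics.

## Psychophysical analysis

Every press is matched to the nearest inclusion center (Euclidean, X–Y);
TP iff distance ≤ tolerance (boundary inclusive), default 10 mm = the
inclusion diameter, swept over {5, 10, 15, 20} mm. TP counts are
non-decreasing and FP counts non-increasing in tolerance by set inclusion.
**Accuracy** is TP/(TP+FP) by default. The alternative reading "TP over
(responses minus FP)" is available behind `definition="literal"`, but it
reduces to TP/TP = 1 whenever any TP exists, so it cannot be the intended
quantity; the discrepancy is documented rather than silently resolved.
Per-material identification is binary per inclusion (≥ 1 matching TP) with
the session's denominator the number of inclusions of that material;
multiple presses on one inclusion therefore affect TP/FP counts but not
identification rates, keeping the two analyses independent. Rates are
averaged across sessions (not pooled over responses), with IQR across
sessions as the dispersion measure.

The psychometric function G(x) = [1 + exp(−(x − a)/b)]⁻¹ is fitted to rate
vs. stiffness by bounded nonlinear least squares (b ≥ 10⁻⁶;
initialization a₀ = median stiffness, b₀ = half the stiffness range).
Non-convergence and unidentifiable input (all rates equal) are flagged on
the result, never raised. With perfectly separable rates (each level 0 or
1) the optimum is an infimum as b → 0 and the fit honestly reports
non-convergence; the threshold estimate is still interpretable. Asymptotic
standard errors come from the Gauss–Newton Jacobian when the problem has
positive residual degrees of freedom.

## What the simulation does and does not show

The synthetic sessions emulate the *structure* of the experiment — phantom
geometry and stiffness table, control law, 0.5 N protection, 5 kHz
encoding, bounded latency, six-minute raster exploration — but the subject
is a threshold detector, not a human: it has no attention lapses, no
learning, no proprioceptive-tactile integration, and its exploration is
scripted rather than free. Passing tests therefore demonstrate that the
pipeline transmits stiffness information and that the analysis recovers
what the generative model encodes (stiffer materials identified more often;
a fitted threshold between the soft and stiff stiffness pairs, around
2.9–3.4 N·mm⁻¹ across seeds); they do not reproduce, and are not claimed to
reproduce, human identification percentages or human perceptual thresholds.

## Problem sizes and numerical choices

Default test and acceptance runs use 120 s sessions (five for the
end-to-end analysis), 5 indentation trials per site, 100 Bernoulli
replicates at n = 200 per stimulus level for parameter recovery, and a
0.01 ms reference step for the integration check — sizes at which every
statistic of interest is stable to well within its test tolerance.
Determinism is enforced at the byte level on serialized logs; text
serialization uses `repr` round-tripping of doubles so equality is exact,
not approximate. Degenerate inputs are rejected early: < 3 or collinear
points for enclosed areas, < 2 points for slope estimation, zero responses
for accuracy, non-finite neuron states, patterns exceeding the workspace
or the speed clamp.
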