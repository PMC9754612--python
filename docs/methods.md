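# Methods

## Setting

`quatgeo` analyzes three-dimensional *rotational* hand movements — the
orientation-matching component of object manipulation — represented as
discrete-time unit-quaternion trajectories {q_i}. Two analyses are
supported end to end:

1. **Geodicity of single rotations.** Whether a movement follows the
   shortest great arc (geodesic) on the 3-sphere of unit quaternions,
   quantified by the Quaternion Geodicity Score.
2. **Adaptation to a rotational visuomotor perturbation.** A fixed
   rotation q_r is applied to the hand's instantaneous (extrinsic)
   rotation axis before rendering the visual cursor; adaptation,
   transfer across a 90° change of initial orientation, and washout are
   quantified by aiming axes and aiming angles with spherical statistics.

## Quaternion conventions

Quaternions are stored scalar-first, (s, x, y, z). q and −q encode the
same rotation (double cover); constructors return the s ≥ 0 hemisphere,
while sampled trajectories use sign-continuity enforcement instead
(successive 4-vector dot products ≥ 0), because temporal continuity, not
a canonical hemisphere, is what downstream differencing needs.

* Angular distance: dist(q1, q2) = 2 arccos |Re(q2 q1⁻¹)| ∈ [0, π],
  evaluated in the arctangent form 4 arctan2(‖q1 − q2′‖, ‖q1 + q2′‖)
  (q2′ sign-aligned), which keeps ~1e−16 precision near zero where the
  arccosine bottoms out near 1e−8. Note the closed interval: the formula
  attains π for orthogonal quaternions (half-turn rotations), although
  the distance is sometimes quoted on [0, π).
* Geodesic: q(h) = q1 (q1* qN)^h, h ∈ [0, 1], with the power computed
  through the axis–angle (exp/log) maps; the vector part uses the exact
  ratio sin(h θ/2)/sin(θ/2) with a first-order fallback (ratio → h) when
  sin(θ/2) < 1e−8. Endpoints closer than π − 1e−6 to antipodal raise an
  error (the geodesic is not unique).
* Transition quaternions: extrinsic q_{i+1} = q^δ q_i, intrinsic
  q_{i+1} = q_i q^δ; both share the rotation angle, only axes differ.
* Matrix conversion: hand-written Shepperd method with the
  largest-diagonal-pivot branch (stable near half-turns); matrices must
  be orthonormal with det +1 within 1e−6.

## Preprocessing pipeline

Raw recordings (nominally 1 kHz rotation matrices) are slerp-resampled
onto a uniform 1 kHz clock, downsampled to 100 Hz, converted to
quaternions, and differenced into angular velocity
ω_i = (θ_i^δ/Δt) n̂_i^δ (forward differences, N−1 samples timestamped at
interval starts, so ‖ω_i‖Δt equals the step's angular distance exactly).
Velocity components are low-pass filtered channel-wise with a 4th-order
Butterworth at 6 Hz applied forward–backward (zero phase; effective
attenuation is the squared magnitude response; reflective padding of
3·(order+1) samples). The frame in which ω is filtered defaults to
extrinsic and is exposed as an option.

Segmentation uses strictly-greater threshold comparisons. Untimed
orientation matching: window from the first sample above 10% of peak
speed to a 400 ms dwell of the cursor-to-target distance below 15°
(dwell thresholds are parameters). Fast single rotations: onset at the
first sample above 0.25 rad/s, offset at the first sample back below
0.25 rad/s after the speed has exceeded 1 rad/s.

## Geodicity score

QGS = Σ dist(q_i, q_{i+1}) / dist(q_1, q_N) ≥ 1, with equality exactly
on geodesics (the distances telescope). Endpoint distances below
1e−6 rad raise a degenerate-trial error rather than returning ∞. The
score is computed on raw (unfiltered) 100 Hz quaternions; for fast
rotations the window runs from movement initiation to the time of peak
angular speed, for untimed matching the full segmented trial is used.
A trial counts as geodetic when QGS < 1.2 (strict): with ~50° rotations
this allows roughly a 10° detour. Per-participant summaries use the
median (the distribution is strongly right-skewed) with a percentile
bootstrap 95% CI (default 10,000 resamples, explicit seed).

## Perturbation and compensation

The visuomotor rotation q_r (training value: 60° about x̂) maps the
instantaneous axis to n̂_p = q_r n̂ q_r⁻¹, leaving per-step angles
untouched — so a geodetic movement renders as a geodetic cursor movement
about the rotated axis, with an identical (delayed) speed profile.
Compensation follows from the conjugation algebra: rotating the hand
about n̂_c = q_r⁻¹ n̂_t q_r makes the cursor reproduce the ideal geodesic
toward n̂_t exactly; the same conjugation predicts the full-aftereffect
axis after perturbation removal.

**Rendering contract.** The instantaneous axis is ill-defined at low
speed, so the original apparatus derived it from a transition delayed by
80 samples of the 4 kHz haptic loop (20 ms, below detection). The exact
integration used on screen is not specified anywhere, so this module
defines one explicit contract: the hand sequence is read with a lag of D
samples (the cursor holds its initial orientation for the first D
samples; movements start from rest, so the held segment is smooth), each
per-sample transition of the delayed sequence has its axis replaced by
the perturbed axis and its angle kept, steps with angles below
1e−10 rad reuse the previous valid axis, and the rebuilt steps integrate
extrinsically from cursor₀ = hand₀. With the identity perturbation and
zero delay the cursor equals the hand to machine precision, and the
cursor speed trace lags the hand's by exactly D samples.

## Aiming metrics

Every analyzed trial is pre-rotated by q₁⁻¹ so it starts at the
identity; the **aiming axis** is ω/‖ω‖ at the (first) maximum of the
filtered angular speed, reported in the intrinsic frame by default
(extrinsic optional). Peak speeds below 0.25 rad/s are rejected as
no-movement.

Baseline correction works on the sphere: the per-participant baseline
axis is the normalized vector sum of the aiming axes of 20 randomly
chosen trials out of the last 40 of each baseline set (seeded), and all
axes of the matching sessions (BL1 corrects BL1+TRN, BL2 corrects
BL2+TFR) are rotated by the single rotation taking the baseline axis
onto the session's ideal axis — an isometry, so relative geometry is
untouched.

The **aiming angle** is the elevation of the aiming axis out of the
plane spanned by the perturbation axis n̂_r and the ideal axis n̂_id:

    arctan2( n̂_a · (n̂_r × n̂_id), sqrt((n̂_a·n̂_r)² + (n̂_a·n̂_id)²) ) ∈ [−π/2, π/2]

implemented exactly in this form (the denominator is not a strict
projection when n̂_r and n̂_id are non-orthogonal; in the supported
protocols they are orthogonal). Sign convention: positive toward
n̂_r × n̂_id. With the training geometry (n̂_r = x̂, extrinsic-group ideal
axis) compensation appears at *negative* aiming angle; published figures
of such experiments often plot the compensatory direction as positive,
which is a plotting convention, not a different quantity.

Stage summaries average k = 1–10 consecutive trials per key stage of the
420-trial protocol (FML 1–60, BL1 61–120, BL2 121–180, TRN 181–360,
TFR 361–420); for k = 3 the blocks are 118–120, 178–180, 181–183,
358–360, 361–363, 418–420. Stage axes are normalized vector sums with
each trial axis sign-aligned to the stage's ideal axis first (the double
cover leaves the raw sign ambiguous for noisy near-degenerate
movements); stage angles are arithmetic means.

## Spherical statistics

Aiming-axis samples are modelled as von Mises–Fisher on S²: μ̂ is the
resultant direction and κ̂ = R̄(3 − R̄²)/(1 − R̄²) (capped at 1e6 for
degenerate, all-identical samples).

* **Equal mean directions, unequal concentrations** (g ≥ 2 samples):
  T = 2(Σ κ̂_i R_i − ‖Σ κ̂_i r_i‖) referred to χ² with (p−1)(g−1) = 2(g−1)
  degrees of freedom (r_i the resultant vector, R_i its length). This is
  the weighted-resultant heterogeneous test of the directional-statistics
  literature; an optional bootstrap calibration rotates each sample onto
  the pooled mean and resamples within sample. The df convention
  (3−1)(g−1) is adopted throughout, pairwise comparisons run as g = 2.
* **Specified mean**: vMF log-likelihood ratio of free vs fixed mean,
  with κ under the null re-estimated from the resultant component along
  μ₀ using the same approximation; the null distribution is calibrated
  by parametric bootstrap from vMF(μ₀, κ̂₀) (default B = 999, seed
  mandatory), p = (1 + #{T_b ≥ T})/(B + 1).

Both tests report the angular distance between the compared mean
directions in degrees as the effect size (≥ 15°, the task's accuracy
criterion, is considered large). Both are exactly invariant under a
global rotation of all axes (given fixed seeds): the statistics depend
on the data only through rotation-equivariant resultants.

## Synthetic data

The generator defines the study conditions rather than being tuned to
them:

* Single trials follow the geodesic with minimum-jerk timing
  h(τ) = 10τ³ − 15τ⁴ + 6τ⁵ (peak normalized speed 1.875 at τ = 0.5,
  bell-shaped speed, zero endpoint velocity/acceleration).
* Noisy trials perturb the per-step transition axes by unit-variance
  Gaussian noise smoothed with a ~150 ms Hann window and rescaled to a
  standard deviation of `noise_axis_sd` (default 2°), then re-integrate;
  a smoothly ramped terminal correction maps the drifted endpoint back
  onto the target (accepted trials end within the task's 15° cap; the
  generator ends exactly on target). Zero noise reproduces the geodesic
  bit-for-bit. Mean QGS increases monotonically with the jitter level.
* Trial magnitudes: 50° fixed for the adaptation protocol, U[40°, 60°]
  for orientation-matching simulations; durations U[400, 600] ms,
  matching the task's timing-feedback window; sampling at 100 Hz (the
  analysis rate) except where the 4 kHz haptic rate is itself under
  test.
* The cohort simulator runs the 420-trial protocol per participant. The
  learner is a deliberately simple single-state model — aim rotates
  about n̂_r exponentially toward the compensation axis with per-trial
  rate 0.2 up to an asymptote of 40° (partial adaptation; the 15°
  success window caps useful compensation below the full 60°), and
  decays by a retention factor 0.95 per washout trial (slow washout).
  Group semantics: *extrinsic* learners attach the learned rotation to
  the extrinsically represented axis, so it transfers across the 90°
  change of initial orientation; *intrinsic* learners attach it to the
  body-fixed axis, so the transfer session shows no aftereffect;
  *control* keeps the first initial orientation but faces an orthogonal
  target (narrow generalization → no aftereffect). These are the
  qualitative transfer signatures the analysis pipeline must recover;
  the learner is fixture machinery, not a scientific claim about humans.

What the generator does **not** emulate: online corrections and
feedback-driven submovements, trial-to-trial duration/amplitude
correlations, recording dropouts, and any implicit/explicit learning
decomposition. Passing tests therefore demonstrate correctness of the
measurement pipeline under known ground truth, not validity of any
claim about human data.

## Numerical and testing choices

* Unit-norm tolerances: 1e−9 internal, 1e−6 on file load. Degeneracy
  guards: QGS endpoint distance 1e−6 rad, antipodal geodesics π − 1e−6,
  per-step axis extraction 1e−10 rad.
* Problem sizes in the test suite are chosen to keep the full run a few
  minutes on one CPU while leaving no claim untested at its stated
  tolerance: bootstrap-CI coverage uses 1000 simulated samples (n = 100,
  500 resamples); both type-I-error checks use 2000 null simulations,
  the bootstrap-calibrated test with B = 199 (p-value validity holds for
  any B; B = 999 stays the analysis default); aiming-axis recovery uses
  500 noisy trials; cohort-level checks average 4–10 simulated
  participants, since k-trial stage noise (motor jitter sd 2°/√k) does
  not average out within a single participant.
* The baseline-axis concentration check asserts ≥ 95% of baselines
  within 5° of μ at κ = 50: the mean of 20 draws has tangent sd ≈ 1.8°
  per component, putting the Rayleigh tail beyond 5° at ≈ 2%.
* scipy's `Rotation` is used in tests as an independent oracle for
  axis-angle/matrix conversions, never in the implementation; vMF
  *sampling* uses `scipy.stats.vonmises_fisher`, while fitting and both
  tests are implemented here.

## Known limitations

* The rendering contract is one explicit reconstruction of an
  under-specified apparatus behaviour; absolute cursor trajectories of
  other integrations may differ, though the axis remapping, speed
  preservation and 20 ms lag are contract-independent.
* κ̂ uses the moment approximation, adequate for the κ ≳ 10 regime of
  aiming axes but biased near uniformity.
* The heterogeneous mean-direction test relies on a large-κ χ²
  asymptote; at n = 30, κ ≥ 20 its measured type-I error is ≈ 0.06 at
  α = 0.05 (bootstrap calibration is available when that matters).
* Stage numbering assumes the fixed 420-trial protocol; other schedules
  need a custom `StagePlan`.
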