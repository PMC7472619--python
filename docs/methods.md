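# Methods

## Problem and scope

`squatval` reconstructs, end to end, a concurrent-validity study of two 3D
motion-capture routes for the single leg squat: a laboratory optical system
(reflective marker clusters, 120 Hz) serving as the reference, and a wearable
four-sensor IMU tool (orientation quaternions, 50 Hz) as the instrument under
test. Four segments are tracked — trunk (sternal manubrium), pelvis (sacrum),
stance-side thigh and shank — defining three joints: spine (trunk vs sacrum),
hip (thigh vs sacrum, the sacrum cluster standing in for the pelvis), and knee
(shank vs thigh). Five outcome variables are read at the instant of peak knee
flexion: knee flexion, hip flexion, hip ab/adduction ("sway"), spine flexion
and spine lateral flexion. Because the original raw recordings are not
public, the package ships a rigid-body squat simulator whose population
defaults reproduce the study's descriptive scale, and the whole analysis runs
against that simulator with ground truth retained.

## Conventions

All rotations are unit quaternions, scalar-first `(w, x, y, z)`, with
`q1 ⊗ q2` meaning "apply q2, then q1" (`R(q1⊗q2) = R(q1)R(q2)`); `q` and `−q`
are the same rotation everywhere angles are produced. Every segment carries
the same right-handed local frame: x anterior, y longitudinal/superior
(pointing proximally), z to the subject's right. A segment quaternion maps
local vectors into the world frame. At the upright calibration pose all
segment frames coincide with the lab frame; anatomical axis directions are
therefore lab-attached, which encodes the usual protocol requirement that the
subject face a fixed lab direction during calibration. Rotating the recorded
coordinates of an entire session consequently *changes* the reported angles
(the fitted poses conjugate); the invariance that does hold — and is tested —
is that a common world rotation applied to the segment *orientations* leaves
all joint angles unchanged, because relative orientation is left-invariant.

Anatomical signs are applied through a per-joint table of ±1 multipliers:
flexion, adduction (hip/knee), homolateral lateral flexion (spine) and
internal rotation are positive; frontal and transverse multipliers flip
between left- and right-side stance so the labels keep their meaning.

## Joint-angle systems

Both routes start from the same calibrated relative orientation `q` of the
secondary segment in the primary's frame and differ only in the angle
parametrization.

**Euler route (optical).** Intrinsic sequence resolving the sagittal,
frontal and transverse planes in that order: first rotation about the
mediolateral axis, second about the anterior axis, third about the
longitudinal axis. The frontal angle lives in (−90°, +90°); within 1° of
±90° the first and third axes align (gimbal lock) and the output carries a
warning. The decomposition is validated against an independent oracle
(scipy's intrinsic ZXY Euler extraction in the segment basis) and by
compose→decompose round trips.

**Tilt/sway/twist route (sensor).** Let `v` be the image of the secondary
longitudinal axis under `q`. Then

* tilt  = atan2(v·anterior, v·longitudinal) — sagittal-plane angle,
* sway  = atan2(v·lateral, ‖sagittal-plane component of v‖) — elevation of
  the longitudinal axis out of the sagittal plane,
* swing = angle(longitudinal, v) ≥ 0 — total deviation,
* twist = signed angle of the twist factor of the swing–twist decomposition
  of `q` about the longitudinal axis.

Tilt and sway are functions of `v` alone, so they are independent of any
rotation-ordering convention. Defining sway as the *elevation* rather than
the plain frontal-plane projection atan2(v·lateral, v·longitudinal) was a
deliberate design choice: the projection form inflates the frontal angle by
1/cos(sagittal) once the joint is deeply flexed (an 8° frontal angle at 60°
of hip flexion would read ≈ 16°), which is incompatible with the study's
observation that the two systems' frontal-plane numbers agree to a couple of
degrees. With the elevation form, tilt and sway coincide exactly with the
Euler sagittal and frontal angles (they parametrize the same swing of the
longitudinal axis), both reduce to the plane projection for planar motion,
and the cross-system comparison probes genuinely identical quantities while
the transverse components (twist vs third Euler angle) still differ — as in
the original tool, transverse-plane validity is not claimed. The measurement
units glossary: "swing" is reported as the total longitudinal-axis deviation;
the source material lists the unit without defining it, and this is the
natural rotation-order-free total.

Tilt/sway/twist remain finite through the Euler warning region and vary
continuously along any path that does not cross the lateral pole
(|frontal| = 90° exactly), where a sagittal azimuth ceases to exist for any
parametrization; the implementation flags such frames rather than guessing.

**Swing–twist decomposition.** `q = swing ⊗ twist` with the twist axis
parallel to a chosen unit axis and the swing axis orthogonal to it, computed
by projecting the quaternion's vector part onto the axis and renormalizing.
A rotation of exactly 180° perpendicular to the axis has no defined twist;
it is flagged and the twist set to identity. Recomposition to ±q at 1e-9 is
enforced over 10⁴ random rotations in the test suite.

**SLERP.** Constant-angular-speed interpolation along the shorter arc
(negating one endpoint when the 4-vector dot product is negative), falling
back to normalized linear interpolation within 1e-6 of antipodality. Used to
resample the 50 Hz sensor *orientations* onto the 120 Hz optical timeline;
angles are always recomputed after resampling, never interpolated
themselves, since orientation space is where "spherical linear
interpolation" is well defined.

## Calibration

Both systems are zeroed with the subject standing upright for 1 s.

*Optical:* the cluster template of each segment is the centred mean marker
configuration over the (identically filtered) calibration capture, so the
fitted pose of every frame is already the rotation relative to upright; the
per-joint upright relative orientation (≈ identity) is additionally averaged
(hemisphere-aligned chordal mean) and divided out.

*Sensor:* each segment stream is right-multiplied by the inverse of its own
averaged upright reading before relative orientations are formed. Because
the sensor reading is (segment orientation) ⊗ (constant mounting rotation),
this cancels sensor-to-segment mounting misalignment *exactly* — the
alternative of calibrating the relative quaternion after forming it leaves
the motion conjugated by the distal mount (a 5° mount would skew a 75° squat
by ≈ 0.3°). The chordal mean over the 1 s window is adequate because the
calibration orientations are tightly clustered; at zero noise it changes no
downstream angle by more than 0.05° versus any single calibration frame.

## Optical processing chain

Marker gaps up to 0.1 s are filled by per-coordinate linear interpolation;
longer gaps are reported, and a cluster reduced below 3 valid markers for
longer than that is a hard error. Trajectories are filtered with a 4th-order
low-pass Butterworth at 3 Hz applied forward and backward (zero phase, even
reflective padding of up to 1 s per end, trimmed). Zero-phase filtering is
required because the analysis keys on peak *timing*; the effective magnitude
response is the squared single-pass response, giving < 0.1% amplitude change
at the 0.25 Hz squat fundamental and ≈ 84 dB attenuation at 10 Hz. Series
shorter than three dominant filter time constants (3/cutoff s) are rejected.
Cluster orientation per frame is the orthogonal-Procrustes rotation
(SVD with reflection guard, centroid-aligned) from the calibration template,
with per-frame residual RMS attached and a warning above 20 mm.

## Peak extraction

The peak is the global maximum of the knee sagittal curve, ties broken by
the earlier frame, with warnings for endpoint maxima and an error for curves
that never exceed 1°. Each modality reads all five variables at its *own*
peak instant (the original systems produced their summary values
independently); a shared-instant mode is available through configuration.
No sub-sample interpolation is applied: at squat speed the knee curve is
flat near its peak and the 120 Hz frame resolution (8.3 ms) contributes
< 0.01° of error.

## Synthetic data model

Joint-angle time courses follow `peak × sin²(πt/4)` over the 4 s trial
(2 s down, 2 s up, maximum exactly at 2 s) — the smoothest profile
consistent with the metronome protocol; frontal-plane angles share the
sagittal time course scaled to their own peaks, and transverse profiles are
zero. Per-subject peaks are Normal with the study's trial-1 descriptive
means/SDs (knee 73.8 (9.1), hip 60.8 (14.7), hip sway −8.1 (17.1), spine
13.8 (10.9), spine sway 3.8 (5.7) degrees); within-subject between-trial
jitter (SD 3° knee/hip flexion, 2° the rest — field-typical repeatability
values, unstated in the source) is added independently per trial.

The kinematic chain is rooted at the stance ankle with the shank
dorsiflexing by a fixed 0.35 fraction of knee flexion so the chain stays
plausibly balanced; segment lengths are typical adult values. Only relative
orientations enter any measured angle, so these choices affect rendered
marker positions, not outcomes.

Noise model, per modality:

* **Soft-tissue artefact** — for each segment an AR(1) Gaussian process with
  0.5 s correlation time and stationary RMS equal to the configured
  amplitude (thigh 10 mm, others 5 mm — scaled down from the up-to-40 mm
  thigh values reported for skin-mounted markers), split 80% / 20% in
  variance between a cluster-common translation and independent per-marker
  residuals. The common-mode share reflects that tape-mounted plates mostly
  translate with the skin; only the residual share corrupts orientation.
  With the default cluster geometry (120 mm plate, one marker raised 30 mm)
  this puts the per-system knee-angle error near 2°, matching the < 2°
  hip/knee error scale the study reports.
* **Marker white noise** — 0.5 mm isotropic per coordinate (camera jitter;
  essentially removed by the 3 Hz filter).
* **IMU orientation noise** — per-sample random rotation with 1° total
  small-angle SD composed onto each sensor reading.
* **Mounting misalignment** — a constant per-subject random rotation with 5°
  total SD per sensor, identical in trial and calibration captures (and
  hence cancelled by calibration).

What the simulator does *not* emulate: bone-kinematic soft-tissue coupling
(real STA correlates with the movement itself), magnetometer heading drift
between sensors, marker mislabelling, trial-to-trial marker re-application,
and any systematic cross-system bias — the simulated systems share the true
upright pose, so mean differences near zero are expected by construction,
unlike the up-to-5° spine offsets in the original data. Passing tests
therefore demonstrate correctness of the pipelines and the plausibility of
the error *scale*, not field accuracy of any physical instrument.

## Validity statistics

Per variable and trial, over paired per-subject values: mean, SD (n−1) and
t-based 95% CI per system; paired mean difference (new system minus
reference — the direction is fixed and stated, since the source tables are
sign-inconsistent across rows) with t-based CI; Shapiro–Wilk at α = 0.05 on
*both* samples gating Pearson's r (both normal) versus Spearman's ρ
(average ranks for ties); strength labels on |r| with half-open intervals
[0.8, 1) very strong, [0.6, 0.8) moderate, [0.3, 0.6) fair, below 0.3 poor,
and exactly ±1 perfect. Significance is flagged at p < 0.05 per test with no
multiple-testing correction, as in the original analysis; the report footer
says so. t-quantiles (not z) reproduce the printed reference CIs exactly at
one decimal. Report values are rounded to one decimal (degrees) / three
decimals (coefficients).

## Problem sizes and numerical choices

The default study is 44 subjects × 3 trials = 132 trials, processed in a few
seconds per replicate; the stochastic acceptance property re-runs the full
study over 20 seeds, and the acceptance script summarises 10 replicate
studies. Tolerances used throughout: quaternion norms restored to 1e-9 after
every operation; swing–twist recomposition at 1e-9; noise-free end-to-end
recovery at 0.2° for peak knee flexion (the residual is filter passband
ripple and 50→120 Hz interpolation error at the 0.25 Hz fundamental) and
0.5° for all variables; cross-modality agreement at 0.3°. Hemisphere
continuity is enforced on all quaternion streams on read; IMU norms off by
more than 1e-2 abort, beyond 1e-6 renormalize with a logged warning.

## Known limitations

* Anatomical axes are lab-attached at calibration; subjects misaligned with
  the lab at calibration bias all angles (by design, matching the optical
  protocol).
* The hip uses the sacrum cluster as pelvis proxy — only four instrumented
  sites exist — so "hip" angles include lumbo-pelvic motion.
* Transverse-plane outputs (twist / third Euler angle) are produced but not
  validated against each other; the two parametrizations genuinely differ
  there.
* The simulator's between-trial jitter and noise amplitudes are modelling
  choices, not estimates from the original recordings.
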