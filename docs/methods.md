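# Methods

## Problem setting

An end-effector-based rehabilitation robot (e.g. a cable-driven arm-weight
support) attaches only to a distal limb segment — here the forearm — and
therefore measures only that segment: the positions of its two cuffs, from
which the elbow position `p_E` in the robot workspace frame R follows by
extrapolating the cuff line (`p_E = l_p · normalize(p_P − p_W) + p_P`).
Nothing is measured about the adjacent segment (the upper arm) or its free
endpoint (the shoulder).  The conventional workaround assumes the shoulder
stays pinned at a nominal position recorded at the start of therapy, which
fails exactly when it matters: when the patient compensates weak shoulder
and elbow joints with trunk or shoulder-girdle motion.

`armfusion` estimates the upper-arm orientation, the elbow angle and the
shoulder position in R by fusing a single wearable IMU on the upper arm with
the robot's elbow position stream — without magnetometer readings, which are
unreliable indoors and near robots.

## Frames and conventions

Quaternions are scalar-first, Hamilton convention; rotation acts as
`q ⊗ v ⊗ q*`.  All frames are right-handed with z pointing straight up:

* **R** — robot workspace frame (y horizontal forward);
* **A** — upper-arm/IMU frame; its x-axis runs along the segment toward the
  elbow;
* **I** — the inertial reference frame of the magnetometer-free orientation
  filter: vertical z-axis, but an *arbitrary, slowly drifting* heading.

Angles are radians internally and degrees at every user interface.

## Orientation filter (frame I)

A complementary accelerometer-corrected strapdown filter: the quaternion is
propagated by the exact exponential of `ω·dt` and tilted toward agreement of
the rotated specific-force direction with the vertical, by a rotation about
a horizontal axis at rate `gain · tilt_error`.  Because the correction axis
is horizontal, the heading is never corrected: it is unobservable without a
magnetometer and drifts with the integrated gyroscope bias (tenths of a
degree per second for MEMS units).  Initialization is the tilt implied by
the first accelerometer sample with heading zero; no rest phase and no bias
calibration are required — any initial heading choice is absorbed by the
offset δ below.

**Correction gain** (default `0.2 s⁻¹`, i.e. a 5 s time constant): the
steady-state inclination error under a horizontal bias component `b_h` is
≈ `b_h / gain` (≈ 0.7° for 0.15 deg/s), while motion acceleration at the
task's 0.2–1 Hz leaks into the tilt attenuated by ≈ `gain/ω` (< 0.5° here).
A much smaller gain would let realistic biases tilt the estimate by tens of
degrees; a much larger one would follow the motion acceleration.  Samples
with near-zero specific-force norm (free fall) skip the correction.

## Heading-offset estimation (frames I → R)

I and R share the vertical axis, so they differ by one drifting angle δ(t).
δ is inferred by comparing two measurements of the same physical quantity,
the elbow acceleration:

* **IMU route** — the measured specific force is shifted from the sensor to
  the elbow with the rigid-body terms `([ω]×)² p + [ω̇]× p` (p = IMU-to-elbow
  offset in A, default 0.15 m along the segment), rotated into I with the
  filter quaternion, and gravity `[0,0,9.81]` is removed.
* **Robot route** — the second central-difference derivative of the 25 Hz
  elbow position.

Both signals pass identical causal 5th-order Butterworth low-passes at
0.5 Hz, so their group delays cancel in the disagreement
`d(δ) = Rz(δ) a_I − p̈_R`.  The windowed cost `c(δ) = Σ‖d‖²` over the last
20 s (m = 500 pairs at 25 Hz; the 100 Hz IMU signal is matched to robot
timestamps by nearest-sample selection) is minimized over heading grids:

* every 5 s of stream time, if the motion gate opens;
* **motion gate**: the 20 s window is split into five 4 s sub-windows; a
  sub-window "moves" when the elbow leaves a sphere of 0.10 m *diameter*
  (max pairwise distance > 0.10 m); at least 3 of 5 must move.  Without
  motion the heading is unobservable (a purely vertical `a_I` gives a
  δ-independent cost) and the estimate is held;
* **unconverged**: two-step search — full circle at 5° spacing, then ±5° at
  1° around the coarse minimum.  Converged once five consecutive gated
  estimates each change by ≤ 5° (wrapped);
* **converged**: single ±5°/1° search around the previous estimate.  Drift
  between updates (≈ 1.5°–2.5° at realistic bias rates) stays well inside
  the ±5° grid; hits of the grid edge are logged as warnings.  A fallback to
  the two-step update is deliberately not implemented — the refined grid
  never saturates under the operating conditions, and the edge warning
  surfaces the condition if it ever did.

Ties in the grid argmin break toward the smallest wrapped angle, making
degenerate windows deterministic.  The 1° refinement spacing sets the
attainable accuracy floor.

**Group-delay alignment of ω̇.**  The angular acceleration is obtained by
central-differencing the 2.5 Hz low-pass-filtered gyro signal.  A causal
filter delays that term by ≈ 0.19 s relative to the unfiltered accelerometer
and radial terms it is summed with; on noise-free simulation this misalignment
alone rotated the cost minimum by ≈ 2.5°, more than the grid resolution.
`gyro_derivative` therefore advances the filtered derivative by the filter's
known DC group delay.  This uses only already-measured samples and the
heading update is retrospective over a 20 s window, so real-time feasibility
is unaffected; the trailing ~0.19 s of the window holds the last aligned
value.

## Pose reconstruction (frame R)

With `δ̂` held piecewise-constant between updates (drift over 5 s is ≈ 2.5°
at 0.5 deg/s, within tolerance):

* `q_RA = Rz(δ̂) ⊗ q_IA` — upper-arm orientation in R;
* elbow angle `ϑ = ∠(x_C, q_RA ⊗ x̂ ⊗ q_RA*)`, with `x_C` the forearm axis
  from the cuff line; computed via `atan2(‖cross‖, dot)`, which is exact in
  [0°, 180°] and safe near the boundaries where `acos` loses precision;
* `p_S = p_E − q_RA ⊗ (l_A x̂) ⊗ q_RA*` — the shoulder one segment length
  (default l_A = 0.30 m) behind the elbow.  A heading error of 1° moves the
  endpoint by at most the chord `2 l_A sin(0.5°)` < 1 cm for l_A ≤ 0.5 m.

Before the first gated update δ̂ is undefined and poses are flagged invalid
rather than fabricated.  The *conventional* baseline (fixed nominal
shoulder, arm axis from nominal shoulder to measured elbow) is emitted
alongside for comparison; by construction its shoulder error equals the
actual shoulder displacement.

## Compensatory-motion detection

Proper executions of cyclic reaching show shoulder displacements around
4 cm; compensatory executions (trunk lean, shoulder-girdle substitution)
around 14 cm.  Each completed cycle is classified from the estimated
shoulder: **compensatory** iff the Euclidean displacement from the nominal
position exceeds a 0.10 m radial tolerance for *strictly more than* 20% of
the cycle (time-weighted; excursions up to exactly 20% are tolerated).
Displacement is the full 3-D distance by default; a planar flag restricts it
to the horizontal plane for comparison against an overhead camera.  Cycles
containing invalid poses are reported unclassifiable, never guessed.
Cycle boundaries are inputs (the task is a known repetitive exercise); no
automatic segmenter is provided.

The per-sample biofeedback signal is green inside the tolerance, blue
immediately after leaving it, and orange once outside for longer than a
maximum tolerated duration (defaulting to a fraction of the cycle duration;
20% of a typical cycle ≈ 1 s).

## Synthetic data generator

The generator emulates the desk-scale study conditions so the entire
pipeline is testable without hardware:

* hand path: a 0.40 × 0.24 m rectangle (box outline on a table) centered
  0.33 m in front of the nominal shoulder, traced counterclockwise at
  constant perimeter speed with period 4.6 s (proper) / 5.4 s
  (compensatory), then low-passed (zero-phase, 1 Hz) into a
  twice-differentiable trajectory;
* shoulder: displaced horizontally toward the instantaneous hand position
  with a raised-cosine profile phase-locked to the cycle, peaking at the
  configured amplitude (0.04 m proper / 0.14 m compensatory).  Directing
  the displacement toward the hand emulates a trunk lean and keeps the path
  reachable at 14 cm displacement;
* elbow: planar two-link inverse kinematics (upper arm 0.30 m, forearm
  0.28 m, elbow-right branch), so `‖p_S − p_E‖ = l_A` holds exactly;
  unreachable configurations raise;
* IMU (100 Hz): body-frame angular rate from central differences of the
  quaternion log map, plus a constant bias (default magnitude 0.34 deg/s
  along the vertical-dominant direction `[1,−1,3]/√11`, giving ≈ 0.31 deg/s
  heading drift plus a realistic horizontal component) and white noise
  (0.5 deg/s RMS); specific force at the sensor point plus white noise
  (0.05 m/s² RMS); optional ≤ 1 Hz soft-tissue position jitter (off by
  default);
* robot (25 Hz): elbow and both cuff positions with 5 mm RMS white noise.

Everything derives from a single seed; identical configurations are
bit-identical.

**What the generator does not model**, and hence what passing tests do not
show about real data: rope oscillations and slack-rope outliers in the cuff
positions, non-planar and out-of-plane arm motion, gyroscope bias
instability and scale errors, soft-tissue rotation artifacts (only
translational jitter is available), and anatomical joints with more than
the modeled degrees of freedom.  The noise magnitudes are plausible MEMS /
cable-robot values, not measured ones, and are configurable precisely so
robustness can be probed by varying them.

## Evaluation harness and problem sizes

Metrics follow robust-statistics reporting: medians with 5th/95th
percentiles, time-based and cycle-based, per method.  The reference
classification experiment runs one proper and one compensatory trial sized
to yield 40 post-convergence cycles each (52 cycles generated per trial;
convergence takes the first 20 s window plus five gated updates, ≈ 45 s),
classifies every post-convergence cycle and summarizes the per-cycle mean
shoulder error.  These sizes keep a full run in seconds while exceeding the
80-cycle scale used for the headline checks.  The sensitivity harness
re-runs the tracker with mismatched assumptions — IMU-to-elbow offset
±7.5 cm, upper-arm length ±2.5 cm, gyro-filter cutoff ±1 Hz — against
unchanged measurements and reports median-metric deltas; segment-length
mismatch leaves the elbow angle untouched (it enters only the endpoint
equation), and cutoff changes are near-negligible.

## Known limitations

* Heading is only observable during motion with non-collinear horizontal
  acceleration; the motion gate handles rest, but slow quasi-static motion
  below the gate threshold simply freezes δ̂ while it keeps drifting.
* The ±5° one-step grid assumes drift < 5° per 5 s update; faster drift
  (bias ≫ 1 deg/s) would saturate the grid (logged, not auto-recovered).
* Sensor-to-segment alignment is assumed done upstream; misalignment maps
  directly into elbow-angle and endpoint errors.
* The detector needs cycle boundaries from the task definition.
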