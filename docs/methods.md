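# Methods

This note documents the models, the synthetic data, and the numerical and
design choices in `stairhip`, in the spirit of a package methods appendix.

## Estimation problem and network

The package estimates four outputs per timestep — sagittal hip angle (deg),
sagittal hip moment (Nm/kg), frontal hip angle (deg), frontal hip moment
(Nm/kg) — from 28 wearable inputs: the 13 channels of a shank IMU and of a
thigh IMU (3D accelerometer m/s², gyroscope rad/s, magnetometer a.u.,
scalar-first unit quaternion), the dominant-foot vertical GRF (N), and the
activity duration (s, constant within a trial and retained as a feature even
though it min–max scales to zero within one trial).

One multi-output network serves all four targets (rather than four separate
nets): a 28–5–5–4 feed-forward net, tanh hidden layers, linear output.
Inputs *and* outputs are min–max scaled to [−1, 1]; output scaling balances
the joint loss across units (degrees vs Nm/kg). Constant feature columns map
to zero and are flagged but kept, so the feature layout never changes.

Training is full-batch Levenberg–Marquardt on the scaled residuals with an
analytic Jacobian. Defaults: λ₀ = 10⁻³, ×10 on rejected steps, ×0.1 on
accepted ones, λmax = 10¹⁰, at most 120 epochs. The stopping rule follows
the wearable-ANN recipe: training stops once the infinity-norm of the error
gradient has failed to improve its running minimum for more than six
consecutive passes ("gradient stall"). Accepted steps strictly decrease the
SSE, so the final model never fits worse than the initial one. Weights are
initialized with the Nguyen–Widrow rule (hidden rows rescaled to norm
0.7·H^(1/n_in), biases uniform within that bound); the linear output layer
starts with small uniform weights. Everything is seeded; identical seed and
data give bitwise-identical fits single-threaded.

## Pre-processing pipeline

Mirroring the laboratory recipe: 4th-order zero-phase (forward–backward)
Butterworth low-pass filters — 10 Hz for insole and IMU vector channels,
6 Hz for marker trajectories, 2.3 Hz for the shank gyro channel used in
event detection. Quaternion channels are not filtered (they stay unit-norm).
Butterworth order is a package choice (the method names only the cutoffs);
zero-phase application avoids shifting detected events. The 100 Hz insole is
linearly resampled onto the 128 Hz IMU clock (output length
⌊(N−1)·128/100⌋+1). The shank IMU is worn anteromedially and rotated about
its longitudinal axis to the pure-lateral orientation using the per-subject
goniometric angle (cohort 121.3 ± 6.6°); the rotation is applied to all
vector channels and composed into the quaternion so the implied lab-frame
vectors are unchanged.

Event detection per modality:

* **Insole**: heel strike at upward, toe off at downward crossings of the
  20 N threshold; crossing times are linearly interpolated between samples;
  stance fraction = (TO − HS)/(next HS − HS).
* **Heel marker**: swing = anteroposterior velocity > 0.2 m/s sustained for
  ≥ 0.1 s (threshold configurable); heel strike = first downward zero
  crossing of AP velocity ending a swing.
* **Shank IMU**: within each candidate stance region, the first (in time) of
  the two deepest local minima of the mediolateral angular velocity, with
  parabolic sub-sample refinement. Regions come from insole stance windows
  when available (padded backward by 8 % of a cycle so the contact dip is
  inside the window), otherwise from successive gyro swing peaks.

All streams are shifted so their first heel strikes align with the
marker-based heel strike, cropped to the common interval and re-gridded at
128 Hz. Cycles are linearly resampled to a 101-point gait-percent vector
(0–100 % inclusive — the field convention, which makes the 0/30/60/80 %
comparison points exact grid nodes). Incomplete first/last cycles are
discarded and logged.

## Planar inverse-dynamics surrogate

The gold-standard workflow is represented by a three-segment planar chain
(thigh, shank, foot) hanging from a pelvis-fixed hip, with Dempster segment
parameters (mass fractions 0.100/0.0465/0.0145; COM at 0.433/0.433/0.500 of
segment length from the proximal joint; radii of gyration
0.323/0.302/0.475) and Drillis–Contini segment lengths
(0.245/0.246/0.152 × stature). Sagittal moments come from bottom-up
Newton–Euler recursion with the vertical GRF as the only external load,
applied at the talus (the ankle joint centre) — deliberately reproducing the
gold standard's centre-of-pressure simplification, including its lever-arm
sensitivity (an optional anterior talus shift increases extension-phase
moment magnitudes monotonically). The frontal plane is quasi-static: the
limb is tilted by the hip adduction angle and inertial terms about the AP
axis are neglected (frontal accelerations are small and no frontal dynamic
model is prescribed). Sign conventions: flexion/adduction positive for
angles; moments are the internal (reaction) net moments with flexion and
adduction positive, so stance-phase extension and abduction support appear
negative. The implementation agrees with an independent static free-body
oracle to < 10⁻⁶ Nm/kg and is invariant under mass scaling of subject and
load (Nm/kg output).

## Synthetic cohort generator

The generator emulates the study conditions: 17 subjects with height
~N(1.74, 0.08) m and mass ~N(81.6, 19.5) kg (positive-truncated), one 30 s
trial per subject at 128 Hz (IMUs, markers) and 100 Hz (insole), cycle
duration ~N(2.21, 0.30) s — i.e. 4.53 ± 0.62 cycles per 10 s — clipped to
[1.2, 4.0] s, stance fraction ~N(0.67, 0.034), shank-mount angle
~N(121.3, 6.6)°.

Ground-truth curves are periodic cubic splines over gait percent, calibrated
so the headline features hold exactly on a dense grid: sagittal angle maximum
58.0° at heel strike with range 55.6°; frontal angle range 17.4°; sagittal
moment peak flexion +1.0 Nm/kg near 50 % gait and peak extension near 20 %;
frontal moment with a double abduction bump in stance whose first peak
(−1.6 Nm/kg) exceeds the second, and −1.3 Nm/kg at 30 % gait. Ranges are
calibrated affinely, moment peaks multiplicatively. Per-subject jitter:
amplitude scaling about the curve mean (SD 6 %) plus small offsets (1° /
0.02 Nm/kg); sensor noise defaults (white, additive): gyro 0.02 rad/s, acc
0.2 m/s², mag 0.005 a.u., quaternion 0.002 rad, GRF 5 N, marker 0.5 mm —
small relative to signal ranges, consistent with consumer-grade hardware.

The vertical GRF template is a smooth double bump over stance anchored so it
crosses the 20 N detection threshold exactly at the cycle boundaries (the
spline value at both stance endpoints *is* the threshold, with the curve
clipped to zero a few ms outside), so the insole detector recovers the
template stance fraction at template resolution.

The shank and foot segment-angle templates are internal fixtures, not claims
about measured stair kinematics. They are co-designed with the detectors:

* the shank mediolateral angular-velocity profile is even about heel strike
  (value(p) = value(100−p)), which makes the contact dip an exact fixed
  point of any zero-phase low-pass filter at any cycle duration, and carries
  exactly two stance minima (shallow contact dip, deep mid-cycle trough) —
  the double-dip signature the IMU detector keys on;
* rate knots are interpolated shape-preservingly (PCHIP on cyclically
  extended knots) and integrated with a mid-cycle zero-mean correction, so
  the angle is exactly periodic without spline ringing near contact;
* a small per-trial foot-angle bump cancels the residual heel
  anteroposterior velocity at contact (computed numerically per subject), so
  the marker detector's zero crossing lands on the true contact time.

Virtual sensors come from forward kinematics of the chain: the gyro is the
segment angular velocity in the sensor frame, the accelerometer the specific
force of the mount point, the magnetometer a constant lab field rotated into
the sensor frame, and the quaternion the sensor-to-lab orientation — all with
the as-worn shank mounting offset.

Ground-truth *moments* are template-defined rather than re-derived from the
template GRF through the inverse-dynamics surrogate. The two are only
approximately consistent; this is deliberate, so the printed calibration
peaks hold exactly, and dynamic consistency of the surrogate is tested
separately against its own oracle.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: soft-tissue artifact, magnetometer disturbance fields,
marker occlusion, cycle-to-cycle within-subject variability (jitter is
per-subject), non-vertical GRF components and centre-of-pressure travel, and
any systematic disagreement between a real gold-standard pipeline and real
wearables. Synthetic LOO-CV scores are therefore an upper bound on, not an
estimate of, real-data performance; the published real-data values are used
only as bounds the clean surrogate must beat.

## Evaluation

R² is 1 − SSres/SStot (squared Pearson correlation available as an option;
the definition of "coefficient of determination" varies across gait-ML
work). rRMSE divides the RMSE by the mean of the two signal ranges, in
percent. Per-iterate metrics are computed on the concatenated
gait-normalized cycles of the held-out subject. Paired t-tests compare
subject-level mean curves at 0/30/60/80 % gait (two-sided, α = 0.05);
all-zero differences give t = 0, p = 1, while non-zero constant differences
are reported as undefined rather than infinite. Violin summaries remove
values outside median ± 1.5·IQR before a Gaussian KDE with Silverman
bandwidth.

LOO-CV uses a canonical subject ordering internally, making the whole
experiment — including its per-iterate seeds — invariant to the order trials
are supplied. Single training failures are recorded and skipped, never
fatal.

## Problem sizes and runtimes

Default experiment: 17 subjects × 10 rounds = 170 fits. Training rows are
subsampled with stride 32 on the 128 Hz grid (≈ 120 rows/subject,
≈ 1 900 rows/fit for 199 parameters); evaluation always uses every sample of
the held-out subject. These sizes keep the full experiment at a few minutes
on one CPU while leaving the network comfortably overdetermined; the stride
is a parameter (`loocv(..., stride=...)`).

## Known limitations

* The frontal-plane surrogate is quasi-static and the frontal kinematic
  chain is a single rigid tilt below the hip.
* Template ground truth and surrogate inverse dynamics are not mutually
  consistent by construction (see above).
* The insole event detector requires the GRF noise SD to be well below the
  20 N threshold; at noise levels of several tens of newtons threshold
  crossing times are no longer meaningful.
* Activity duration is constant across the default cohort, so the feature
  carries no information there; it is retained for schema fidelity.
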