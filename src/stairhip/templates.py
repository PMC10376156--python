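"""Periodic gait-cycle templates for synthetic stair ascent.

Each kinematic/kinetic quantity is represented as a smooth periodic cubic
spline over gait percent (0-100, heel strike at 0).  The default templates
are calibrated so that the headline features of stair-ascent hip mechanics
hold exactly on a dense evaluation grid:

* sagittal hip angle: maximum 58.0 deg at heel strike, range of motion 55.6 deg
* frontal hip angle: range of motion 17.4 deg
* sagittal hip moment: peak flexion moment 1.0 Nm/kg near 50 % gait,
  peak extension moment near 20 % gait (extension negative)
* frontal hip moment: double abduction bump during stance with the first
  (larger) peak at 1.6 Nm/kg magnitude (abduction negative)
* stance occupies 67 % of the cycle by default.

Shank and foot segment-angle templates are fixtures: they are shaped so the
downstream event detectors see realistic structure (a shank mediolateral
angular-velocity dip at heel strike followed by a second stance dip, and a
heel marker whose anteroposterior velocity crosses zero exactly at heel
strike), not claims about measured stair kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator

GAIT_GRID = np.linspace(0.0, 100.0, 20001)

#: reference cycle duration (s); 4.53 cycles per 10 s trial on the stepmill
REFERENCE_CYCLE_S = 10.0 / 4.53

DEFAULT_STANCE_FRACTION = 0.67


class PeriodicCurve:
    """Periodic cubic spline over gait percent with optional affine calibration.

    ``value(p) = gain * spline(p mod 100) + offset``
    """

    def __init__(self, knots_percent, knots_value, gain=1.0, offset=0.0):
        kp = np.asarray(knots_percent, dtype=float)
        kv = np.asarray(knots_value, dtype=float)
        if kp[0] != 0.0 or kp[-1] != 100.0:
            raise ValueError("knot grid must span 0..100")
        if kv[0] != kv[-1]:
            raise ValueError("periodic template needs value(0) == value(100)")
        self.knots_percent = kp
        self.knots_value = kv
        self._spline = CubicSpline(kp, kv, bc_type="periodic")
        self.gain = float(gain)
        self.offset = float(offset)

    def __call__(self, percent):
        p = np.mod(np.asarray(percent, dtype=float), 100.0)
        return self.gain * self._spline(p) + self.offset

    def derivative(self, percent):
        """d(value)/d(gait percent)."""
        p = np.mod(np.asarray(percent, dtype=float), 100.0)
        return self.gain * self._spline(p, 1)

    def calibrated_range(self, lo, hi, grid=GAIT_GRID):
        """Return a copy affinely mapped so dense min/max equal ``lo``/``hi``."""
        v = self(grid)
        vmin, vmax = v.min(), v.max()
        gain = (hi - lo) / (vmax - vmin)
        offset = lo - gain * vmin
        return PeriodicCurve(self.knots_percent, self.knots_value,
                             gain=self.gain * gain,
                             offset=self.offset * gain + offset)

    def calibrated_peak(self, peak, grid=GAIT_GRID):
        """Return a copy scaled multiplicatively so the dense extremum with the
        largest magnitude equals ``peak`` (sign of ``peak`` selects which)."""
        v = self(grid)
        ref = v.max() if peak > 0 else v.min()
        return self.scaled(peak / ref)

    def scaled(self, factor):
        return PeriodicCurve(self.knots_percent, self.knots_value,
                             gain=self.gain * factor, offset=self.offset * factor)

    def shifted(self, delta):
        return PeriodicCurve(self.knots_percent, self.knots_value,
                             gain=self.gain, offset=self.offset + delta)


def _integrated_curve(knots_percent, knots_rate, value_at_zero):
    """Curve whose per-percent derivative follows the given periodic rate knots.

    The rate is interpolated shape-preservingly (PCHIP on cyclically extended
    knots, so steep swing flanks do not ring into the stance dips) and
    mean-corrected so the integral over one cycle is zero, which keeps the
    resulting angle periodic.  Returns ``(angle_curve, rate_samples)``.
    """
    kp = np.asarray(knots_percent, dtype=float)
    kv = np.asarray(knots_rate, dtype=float)
    kp_ext = np.concatenate([kp[:-1] - 100.0, kp, kp[1:] + 100.0])
    kv_ext = np.concatenate([kv[:-1], kv, kv[1:]])
    pch = PchipInterpolator(kp_ext, kv_ext)
    p = np.linspace(0.0, 100.0, 4001)
    rate = pch(p)
    # zero-mean correction localized to a mid-cycle bump (symmetric about
    # 50 %, so an even rate profile stays even) leaving the shape around heel
    # strike untouched by the periodicity fix
    mean = np.trapezoid(rate, p) / 100.0
    bump = np.where((p >= 33.0) & (p <= 67.0),
                    np.sin(np.pi * (p - 33.0) / 34.0) ** 2, 0.0)
    rate = rate - mean * (100.0 / 17.0) * bump
    theta = np.concatenate(
        [[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(p))])
    theta = theta - theta[0] + value_at_zero
    theta[-1] = theta[0]  # exact periodic closure (residual ~1e-12)
    return PeriodicCurve(p, theta), rate


# ---------------------------------------------------------------------------
# default knot tables (gait percent, value)

_SAG_ANGLE_KNOTS = (
    (0, 58.0), (5, 54.5), (15, 38.0), (30, 25.2), (45, 10.0),
    (55, 3.6), (62, 2.6), (70, 8.0), (80, 32.6), (90, 50.0),
    (95, 54.5), (100, 58.0),
)

_FRONTAL_ANGLE_KNOTS = (
    (0, 1.1), (8, 6.2), (16, 5.2), (30, 2.8), (45, 0.0),
    (60, -3.1), (70, -8.2), (80, -4.4), (90, -1.6), (100, 1.1),
)

_SAG_MOMENT_KNOTS = (
    (0, -0.10), (10, -0.62), (20, -0.85), (30, -0.70), (40, -0.10),
    (50, 1.00), (60, 0.62), (70, 0.10), (80, -0.20), (90, -0.17),
    (100, -0.10),
)

_FRONTAL_MOMENT_KNOTS = (
    (0, -0.003), (8, -1.30), (15, -1.60), (25, -1.40), (30, -1.30),
    (38, -1.38), (45, -1.45), (55, -1.00), (62, -0.55), (67, -0.05),
    (75, 0.00), (85, -0.01), (100, -0.003),
)

# Shank mediolateral angular velocity (deg per gait-percent).  The profile is
# even about heel strike (value(p) == value(100 - p)), so the contact dip at
# 0 % is an exact fixed point of any zero-phase low-pass filter at any cycle
# duration.  Stance carries exactly two local minima -- the shallow contact
# dip and a single deep mid-cycle trough -- matching the double-dip signature
# the IMU heel-strike detector keys on; the mirrored forward-rotation humps
# flank the trough (the stance-side hump is cancelled in heel velocity by
# concurrent hip extension).
_SHANK_RATE_KNOTS = (
    (0, -0.12), (6, 0.20), (12, 0.55), (18, 0.75), (24, 0.90),
    (30, 0.55), (36, 0.20), (43, -0.35), (50, -0.90), (57, -0.35),
    (64, 0.20), (70, 0.55), (76, 0.90), (82, 0.75), (88, 0.55),
    (94, 0.20), (100, -0.12),
)
_SHANK_ANGLE_AT_HS = 3.0  # deg from vertical

# Foot segment angle (deg from vertical; ~90 = foot flat). Local minimum at
# heel strike so the base foot rate vanishes there.
_FOOT_ANGLE_KNOTS = (
    (0, 84.0), (5, 84.8), (12, 84.2), (25, 85.0), (45, 88.0),
    (60, 96.0), (70, 106.0), (80, 96.0), (90, 87.0), (95, 84.8),
    (100, 84.0),
)

# Odd localized bump used to cancel residual heel anteroposterior velocity at
# heel strike (foot plantarflex/dorsiflex wiggle around contact), deg.
_FOOT_CORRECTION_KNOTS = (
    (0, 0.0), (3, 1.0), (6, 0.35), (10, 0.0), (50, 0.0),
    (90, 0.0), (94, -0.35), (97, -1.0), (100, 0.0),
)

# Vertical GRF shape in body weights over normalized stance time u in [0, 1],
# excluding the threshold anchoring handled by grf_template().
_GRF_SHAPE_KNOTS = (
    (-0.02, -0.060), (0.0, 0.0), (0.13, 1.12), (0.30, 1.02), (0.50, 0.90),
    (0.70, 1.08), (0.88, 0.55), (1.0, 0.0), (1.02, -0.060),
)


@dataclass(frozen=True)
class TemplateParams:
    """Calibrated ground-truth templates and cohort-level defaults.

    Angle templates are in degrees, moments in Nm/kg, all periodic in gait
    percent.  ``shank_angle``/``foot_angle``/``foot_correction`` are internal
    fixtures used to synthesize sensor streams.
    """

    sagittal_angle: PeriodicCurve
    frontal_angle: PeriodicCurve
    sagittal_moment: PeriodicCurve
    frontal_moment: PeriodicCurve
    shank_angle: PeriodicCurve
    foot_angle: PeriodicCurve
    foot_correction: PeriodicCurve
    stance_fraction: float = DEFAULT_STANCE_FRACTION
    cycle_duration_s: float = REFERENCE_CYCLE_S
    cycle_duration_sd_s: float = 0.30
    stance_fraction_sd: float = 0.034
    amplitude_jitter_sd: float = 0.06
    offset_jitter_deg: float = 1.0
    offset_jitter_nmkg: float = 0.02

    def output_curves(self):
        return {
            "sagittal_angle": self.sagittal_angle,
            "sagittal_moment": self.sagittal_moment,
            "frontal_angle": self.frontal_angle,
            "frontal_moment": self.frontal_moment,
        }


def default_templates() -> TemplateParams:
    """Default stair-ascent templates, calibrated to the benchmark features."""
    sag_angle = PeriodicCurve(*zip(*_SAG_ANGLE_KNOTS)).calibrated_range(
        58.0 - 55.6, 58.0)
    frontal_angle_raw = PeriodicCurve(*zip(*_FRONTAL_ANGLE_KNOTS))
    v = frontal_angle_raw(GAIT_GRID)
    scale = 17.4 / (v.max() - v.min())
    mid = 0.5 * (v.max() + v.min())
    frontal_angle = PeriodicCurve(*zip(*_FRONTAL_ANGLE_KNOTS),
                                  gain=scale, offset=mid * (1.0 - scale))
    sag_moment = PeriodicCurve(*zip(*_SAG_MOMENT_KNOTS)).calibrated_peak(1.0)
    frontal_moment = PeriodicCurve(*zip(*_FRONTAL_MOMENT_KNOTS)).calibrated_peak(-1.6)
    shank_angle, _ = _integrated_curve(*zip(*_SHANK_RATE_KNOTS),
                                       value_at_zero=_SHANK_ANGLE_AT_HS)
    foot_angle = PeriodicCurve(*zip(*_FOOT_ANGLE_KNOTS))
    foot_correction = PeriodicCurve(*zip(*_FOOT_CORRECTION_KNOTS))
    return TemplateParams(
        sagittal_angle=sag_angle,
        frontal_angle=frontal_angle,
        sagittal_moment=sag_moment,
        frontal_moment=frontal_moment,
        shank_angle=shank_angle,
        foot_angle=foot_angle,
        foot_correction=foot_correction,
    )


def grf_template(gait_percent, mass_kg, stance_fraction=DEFAULT_STANCE_FRACTION,
                 threshold_n=20.0, g=9.81):
    """Vertical GRF (N) at the given gait percent(s) for one periodic cycle.

    The curve is a smooth double bump over the stance window and zero through
    swing.  It is anchored so that it passes the detection threshold (20 N)
    rising exactly at 0 % gait and falling exactly at ``stance_fraction * 100``
    % gait: the spline value at the stance endpoints equals the threshold and
    the curve is clipped at zero a few milliseconds outside the window.
    """
    if not 0.0 < stance_fraction < 1.0:
        raise ValueError("stance_fraction must be in (0, 1)")
    p = np.mod(np.asarray(gait_percent, dtype=float), 100.0)
    u = p / (100.0 * stance_fraction)
    tau = threshold_n / (mass_kg * g)
    ku, kv = zip(*_GRF_SHAPE_KNOTS)
    kv = np.asarray(kv, dtype=float)
    ku = np.asarray(ku, dtype=float)
    # anchor: shape value tau at u = 0 and u = 1, negative just outside
    kv_anchored = kv.copy()
    kv_anchored[ku == 0.0] = tau
    kv_anchored[ku == 1.0] = tau
    spline = CubicSpline(ku, kv_anchored)
    out = np.zeros_like(u)
    inside = (u >= 0.0) & (u <= ku[-1])
    out[inside] = spline(u[inside])
    # leading margin: the knot table extends 2 % of stance before u=0, i.e.
    # the rise toward the next heel strike begins a few ms before p wraps to 0
    lead = u - 1.0 / stance_fraction  # same sample re-expressed around p=100
    leading = (lead >= ku[0]) & (lead < 0.0)
    out[leading] = spline(lead[leading])
    out = np.clip(out, 0.0, None) * (mass_kg * g)
    return out if out.ndim else float(out)
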