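"""Quantitative gamma-camera characterisation for 131I imaging.

Three ingredients turn reconstructed SPECT counts into activity:

* the calibration factor Q (cps/MBq) from a large uniform phantom,
* a recovery curve R(v) quantifying partial-volume count losses for small
  objects, measured with fillable inserts of known volume, and
* the paralysable dead-time constant tau, one per count-rate mode for
  cameras that switch behaviour at high rates.

The paralysable detector model relates observed and incident count rates as
obs = inc * exp(-inc * tau); its inverse, the dead-time correction factor
DTF, is the fixed point of DTF = exp(DTF * tau * obs) on the physical
(low-rate) branch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import FitError, ValidationError


@dataclass
class RecoveryCurve:
    """Volume-dependent recovery R(v) = R_max * v^n / (v^n + v50^n).

    A saturating curve: R -> R_max for large volumes, falling toward zero
    below the camera's resolution volume (v50 is the volume of half
    recovery).  ``fallback`` marks a monotone piecewise-linear interpolant
    used when the parametric fit fails.
    """

    volumes_ml: np.ndarray
    R: np.ndarray
    r_max: float = 1.0
    v50: float = 1.0
    n: float = 1.0
    fallback: bool = False

    def __call__(self, volume_ml):
        v = np.asarray(volume_ml, dtype=float)
        if self.fallback:
            order = np.argsort(self.volumes_ml)
            out = np.interp(v, self.volumes_ml[order], self.R[order])
        else:
            vn = v ** self.n
            out = self.r_max * vn / (vn + self.v50 ** self.n)
        return float(out) if np.isscalar(volume_ml) else out


@dataclass
class CameraModel:
    """Complete quantitative characterisation of one camera/collimator set-up.

    ``dead_time_modes`` lists one paralysable tau (seconds) per count-rate
    regime; ``mode_switch_cps`` is the observed rate above which the
    high-count-rate mode is active (None for single-mode systems).
    """

    Q_cps_per_MBq: float
    recovery: RecoveryCurve = None
    dead_time_modes: list = field(default_factory=list)  # [(tau_s, label)]
    mode_switch_cps: float = None

    def __post_init__(self):
        if self.Q_cps_per_MBq <= 0:
            raise ValidationError("calibration factor Q must be > 0")

    def tau_for_rate(self, observed_cps: float) -> float:
        """Dead-time constant applicable at an observed count rate."""
        if not self.dead_time_modes:
            return 0.0
        if self.mode_switch_cps is None or len(self.dead_time_modes) == 1:
            return self.dead_time_modes[0][0]
        if observed_cps > self.mode_switch_cps:
            return self.dead_time_modes[1][0]
        return self.dead_time_modes[0][0]


def calibration_factor(voi_rate_cps: float, activity_conc_MBq_per_ml: float,
                       voi_volume_ml: float) -> float:
    """Calibration factor Q = VOI count rate / decay-corrected VOI activity."""
    if voi_rate_cps <= 0:
        raise ValidationError("voi_rate_cps must be > 0")
    if activity_conc_MBq_per_ml <= 0 or voi_volume_ml <= 0:
        raise ValidationError("activity concentration and volume must be > 0")
    return voi_rate_cps / (activity_conc_MBq_per_ml * voi_volume_ml)


def check_calibration_uniformity(sub_voi_rates, tolerance: float = 0.10):
    """Verify count-rate density is uniform across sub-VOIs of the phantom.

    Returns ``(passed, spread)`` where spread is the maximum relative
    deviation from the mean.
    """
    rates = np.asarray(sub_voi_rates, dtype=float)
    if rates.size < 3:
        raise ValidationError("need at least 3 sub-VOI rates")
    mean = rates.mean()
    if mean <= 0:
        raise ValidationError("sub-VOI rates must have positive mean")
    spread = float(np.max(np.abs(rates - mean)) / mean)
    return spread <= tolerance, spread


def recovery_coefficient(obs_rate_cps: float, Q: float,
                         true_activity_MBq: float) -> float:
    """Recovery R = observed rate / (Q * true activity) for one insert."""
    if Q <= 0 or true_activity_MBq <= 0:
        raise ValidationError("Q and true_activity must be > 0")
    if obs_rate_cps < 0:
        raise ValidationError("obs_rate_cps must be >= 0")
    return obs_rate_cps / (Q * true_activity_MBq)


def fit_recovery_curve(volumes_ml, R_values) -> RecoveryCurve:
    """Fit the saturating recovery model to measured (volume, R) pairs.

    On optimiser failure the curve degrades to a flagged monotone
    piecewise-linear interpolant through the measurements.
    """
    v = np.asarray(volumes_ml, dtype=float)
    R = np.asarray(R_values, dtype=float)
    if v.size < 4:
        raise ValidationError("need at least 4 (volume, R) pairs")
    if len(np.unique(v)) != v.size:
        raise ValidationError("volumes must be distinct")
    if np.any(v <= 0):
        raise ValidationError("volumes must be > 0")

    def resid(x):
        r_max, v50, n = x
        return r_max * v ** n / (v ** n + v50 ** n) - R

    x0 = np.array([min(max(R.max(), 0.1), 1.05), np.median(v), 1.5])
    try:
        sol = optimize.least_squares(
            resid, x0, bounds=([1e-3, 1e-6, 0.1], [1.05, 1e6, 10.0]),
            xtol=1e-12, ftol=1e-12)
        if not sol.success:
            raise FitError(sol.message)
        r_max, v50, n = sol.x
        return RecoveryCurve(volumes_ml=v, R=R, r_max=float(r_max),
                             v50=float(v50), n=float(n))
    except (FitError, ValueError):
        warnings.warn("recovery-curve fit failed; using monotone "
                      "piecewise-linear interpolation", stacklevel=2)
        return RecoveryCurve(volumes_ml=v, R=R, fallback=True)


def interpolate_recovery(curve: RecoveryCurve, volume_ml: float) -> float:
    """Evaluate the recovery curve at a volume, clamped to (0, R_max].

    Volumes below the smallest measured insert are model extrapolations and
    raise a warning.
    """
    if volume_ml <= 0:
        raise ValidationError("volume_ml must be > 0")
    if volume_ml < curve.volumes_ml.min():
        warnings.warn(f"volume {volume_ml} ml below measured range "
                      f"({curve.volumes_ml.min()} ml): extrapolating",
                      stacklevel=2)
    r = float(curve(volume_ml))
    upper = 1.0 if curve.fallback else curve.r_max
    return float(np.clip(r, np.finfo(float).tiny, upper))


def paralysable_rate(incident_cps, tau_s):
    """Observed rate of a paralysable detector: inc * exp(-inc * tau)."""
    inc = np.asarray(incident_cps, dtype=float)
    if np.any(inc < 0) or tau_s < 0:
        raise ValidationError("incident rate and tau must be >= 0")
    out = inc * np.exp(-inc * tau_s)
    return float(out) if np.isscalar(incident_cps) else out


def estimate_tau(activities_MBq, observed_cps,
                 linear_cutoff_cps: float = 10_000.0):
    """Estimate the paralysable dead-time constant from a count-rate series.

    Procedure: (i) a zero-intercept linear fit to points observed below the
    cutoff gives a first estimate of the camera sensitivity (cps/MBq), hence
    of the incident rate at every point; (ii) sensitivity and tau are then
    refined jointly by nonlinear least squares of the paralysable model over
    all points.  The joint refinement removes the residual dead-time bias
    that the nominally "linear" low-rate points still carry.

    Returns ``(tau_s, sensitivity_cps_per_MBq)``.
    """
    A = np.asarray(activities_MBq, dtype=float)
    obs = np.asarray(observed_cps, dtype=float)
    if A.shape != obs.shape:
        raise ValidationError("activities and observed rates differ in length")
    low = obs < linear_cutoff_cps
    if low.sum() < 3:
        raise ValidationError(
            f"need >= 3 points below the linear cutoff ({linear_cutoff_cps} "
            f"cps); got {int(low.sum())}")
    if (~low).sum() < 2:
        raise ValidationError(
            f"need >= 2 points above the linear cutoff ({linear_cutoff_cps} "
            f"cps) to constrain tau; got {int((~low).sum())}")

    # zero-intercept least squares: obs = s * A on the linear regime
    sens0 = float(np.dot(A[low], obs[low]) / np.dot(A[low], A[low]))

    # crude tau from the most saturated point at the initial sensitivity
    i = int(np.argmax(A))
    inc_i = sens0 * A[i]
    crude = max(-math.log(max(obs[i] / inc_i, 1e-12)) / inc_i, 1e-12)

    def resid(x):
        s, tau = x[0], math.exp(x[1])
        inc = s * A
        return inc * np.exp(-inc * tau) - obs

    sol = optimize.least_squares(resid, x0=[sens0, math.log(crude)],
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise FitError("dead-time fit did not converge", trace=sol)
    sens = float(sol.x[0])
    tau = float(math.exp(sol.x[1]))
    if tau < 1e-10 and np.allclose(obs, sens * A, rtol=1e-6):
        tau = 0.0  # numerically linear system
    return tau, sens


def dead_time_factor(observed_cps: float, tau_s: float,
                     tol: float = 1e-9, max_iter: int = 100) -> float:
    """Dead-time correction factor: the fixed point of DTF = exp(DTF*tau*obs).

    Converges on the physical branch (DTF >= 1, below the paralysable
    maximum) by fixed-point iteration from DTF = 1, with a Newton fallback.
    Observed rates at or beyond obs*tau = 1/e admit no correction.
    """
    if observed_cps < 0 or tau_s < 0:
        raise ValidationError("observed rate and tau must be >= 0")
    x = observed_cps * tau_s
    if x == 0:
        return 1.0
    if x >= 1.0 / math.e:
        raise ValidationError(
            f"observed rate * tau = {x:.4f} >= 1/e: beyond the paralysable "
            "maximum, no physical correction exists")
    dtf = 1.0
    for _ in range(max_iter):
        new = math.exp(dtf * x)
        if abs(new - dtf) <= tol:
            return new
        dtf = new
    # Newton fallback on f(d) = d - exp(d*x)
    for _ in range(max_iter):
        f = dtf - math.exp(dtf * x)
        fp = 1.0 - x * math.exp(dtf * x)
        step = f / fp
        dtf -= step
        if abs(step) <= tol:
            return dtf
    raise FitError("dead-time factor iteration did not converge")
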