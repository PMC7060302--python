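"""Multi-exponential time-activity curve fitting and time integration.

Whole-body and lesion/organ clearance after a radiopharmaceutical
administration is modelled as a sum of exponential phases,

    A(t) = sum_j A_j * exp(-lambda_j * t),

with effective decay constants lambda_j (biological clearance combined with
physical decay).  The number of phases is chosen statistically (extra
sum-of-squares F test, or small-sample-corrected Akaike information
criterion), and the time-integrated activity Ã — the total number of
nuclear transformations, in MBq·h — is the closed-form integral of the
fitted model.

Fits are nonlinear least squares started from curve-stripping estimates:
the slowest phase is fitted log-linearly to the tail, subtracted, and the
procedure repeated on the residual for each faster phase.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .errors import FitError, ValidationError

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class ExpModel:
    """Sum-of-exponentials activity model A(t) = sum A_j exp(-lambda_j t)."""

    amplitudes: tuple
    decay_constants: tuple  # effective lambda, 1/h

    def __post_init__(self):
        if len(self.amplitudes) != len(self.decay_constants):
            raise ValidationError("amplitudes and decay_constants differ in length")
        if any(lam <= 0 for lam in self.decay_constants):
            raise ValidationError("decay constants must be > 0")
        if any(not math.isfinite(a) for a in self.amplitudes):
            raise ValidationError("amplitudes must be finite")

    @property
    def n_phases(self) -> int:
        return len(self.amplitudes)

    @property
    def half_lives_h(self) -> tuple:
        return tuple(_LN2 / lam for lam in self.decay_constants)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, lam in zip(self.amplitudes, self.decay_constants):
            out = out + a * np.exp(-lam * t)
        return out


def mono_exponential(A0_MBq: float, half_life_h: float) -> ExpModel:
    """Convenience constructor from an amplitude and effective half-life."""
    if half_life_h <= 0:
        raise ValidationError("half_life_h must be > 0")
    return ExpModel((A0_MBq,), (_LN2 / half_life_h,))


@dataclass
class FitResult:
    """A fitted ExpModel with goodness-of-fit and covariance."""

    model: ExpModel
    rss: float
    dof: int
    covariance: np.ndarray
    weights: str
    times: np.ndarray = field(repr=False, default=None)
    activities: np.ndarray = field(repr=False, default=None)
    merged_phase: bool = False

    @property
    def n_points(self) -> int:
        return len(self.times)

    @property
    def n_params(self) -> int:
        return 2 * self.model.n_phases

    def same_data(self, other: "FitResult") -> bool:
        return (self.n_points == other.n_points
                and np.allclose(self.times, other.times)
                and np.allclose(self.activities, other.activities))


def _strip_initial_values(t, y, n_phases):
    """Curve-stripping initial estimates, slowest phase first from the tail."""
    n = len(t)
    seg = max(3, n // n_phases)
    resid = y.astype(float).copy()
    amps, lams = [], []
    lo = n
    for _ in range(n_phases):
        hi = lo
        lo = max(0, hi - seg)
        tt, yy = t[lo:hi], resid[lo:hi]
        pos = yy > 0
        if pos.sum() < 2:  # stripping degenerate; fall back to crude guess
            lam = (lams[-1] * 5.0) if lams else _LN2 / max(t[-1], 1e-6)
            amp = max(resid.max(), 1e-12)
        else:
            slope, intercept = np.polyfit(tt[pos], np.log(yy[pos]), 1)
            lam = max(-slope, 1e-6)
            amp = math.exp(intercept)
        amps.append(amp)
        lams.append(lam)
        resid = resid - amp * np.exp(-lam * t)
    return np.array(amps[::-1]), np.array(lams[::-1])  # fastest first


def fit_exponentials(times_h, activities_MBq, n_phases: int,
                     sigmas_MBq=None, weight_scheme: str = "unweighted",
                     _allow_merge: bool = True) -> FitResult:
    """Fit an ``n_phases``-exponential model by nonlinear least squares.

    Parameters
    ----------
    weight_scheme : str
        ``"unweighted"`` (default) or ``"1/sigma2"`` using ``sigmas_MBq``.

    At least ``2*n_phases + 1`` points are required (positive degrees of
    freedom); fewer than 3 points per phase triggers a warning.  A negative
    fitted amplitude causes a refit with that phase merged into its
    neighbour (one fewer phase), flagged on the result.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(activities_MBq, dtype=float)
    if n_phases < 1:
        raise ValidationError("n_phases must be >= 1")
    if len(t) != len(y):
        raise ValidationError("times and activities differ in length")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    dof = len(t) - 2 * n_phases
    if dof <= 0:
        raise ValidationError(
            f"{len(t)} points cannot constrain {n_phases} phases "
            f"(need >= {2 * n_phases + 1})")
    if len(t) < 3 * n_phases:
        warnings.warn(f"fewer than 3 points per phase ({len(t)} points, "
                      f"{n_phases} phases)", stacklevel=2)

    if weight_scheme == "1/sigma2":
        if sigmas_MBq is None:
            raise ValidationError("weight_scheme '1/sigma2' requires sigmas")
        w = 1.0 / np.asarray(sigmas_MBq, dtype=float)
    elif weight_scheme == "unweighted":
        w = np.ones_like(y)
    else:
        raise ValidationError(f"unknown weight scheme {weight_scheme!r}")

    amps0, lams0 = _strip_initial_values(t, y, n_phases)
    x0 = np.concatenate([amps0, np.log(lams0)])

    def residuals(x):
        amps = x[:n_phases]
        lams = np.exp(x[n_phases:])
        pred = (amps[None, :] * np.exp(-np.outer(t, lams))).sum(axis=1)
        return w * (pred - y)

    sol = optimize.least_squares(residuals, x0, method="lm",
                                 xtol=1e-10, ftol=1e-10, max_nfev=500 * len(x0))
    if not sol.success:
        raise FitError(f"exponential fit did not converge: {sol.message}",
                       initial_values=x0, trace=sol)

    amps = sol.x[:n_phases]
    lams = np.exp(sol.x[n_phases:])
    if np.any(amps < 0):
        if n_phases == 1 or not _allow_merge:
            raise FitError("negative fitted amplitude", initial_values=x0)
        warnings.warn("negative amplitude: merging phases and refitting",
                      stacklevel=2)
        res = fit_exponentials(t, y, n_phases - 1, sigmas_MBq, weight_scheme)
        res.merged_phase = True
        return res

    order = np.argsort(lams)[::-1]  # fastest phase first
    amps, lams = amps[order], lams[order]
    rss = float(np.sum(sol.fun ** 2))

    # covariance from the Jacobian at the solution, scaled by residual variance
    J = sol.jac
    try:
        cov = np.linalg.inv(J.T @ J) * (rss / dof if dof > 0 else np.nan)
    except np.linalg.LinAlgError:
        cov = np.full((len(sol.x), len(sol.x)), np.nan)

    return FitResult(model=ExpModel(tuple(amps), tuple(lams)),
                     rss=rss, dof=dof, covariance=cov,
                     weights=weight_scheme, times=t, activities=y)


def f_test_select(fit_simple: FitResult, fit_complex: FitResult,
                  alpha: float = 0.05) -> dict:
    """Extra sum-of-squares F test between two nested fits on the same data.

    F = ((rss_s - rss_c)/(df_s - df_c)) / (rss_c/df_c); the more complex
    model is chosen iff p < alpha.
    """
    if not fit_simple.same_data(fit_complex):
        raise ValidationError("F test requires fits on identical data")
    if fit_complex.n_params <= fit_simple.n_params:
        raise ValidationError("fit_complex must have more parameters")
    if fit_complex.rss > fit_simple.rss * (1 + 1e-12):
        raise FitError("complex model has larger RSS than simple model; "
                       "fits inconsistent")
    dfn = fit_simple.dof - fit_complex.dof
    dfd = fit_complex.dof
    if fit_complex.rss == 0:
        F = math.inf if fit_simple.rss > 0 else 0.0
    else:
        F = ((fit_simple.rss - fit_complex.rss) / dfn) / (fit_complex.rss / dfd)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, dfn, dfd)) if math.isfinite(F) else 0.0
    chosen = fit_complex if p < alpha else fit_simple
    return {"F": F, "dfn": dfn, "dfd": dfd, "p": p, "chosen": chosen}


def _aicc(fit: FitResult) -> float:
    n = fit.n_points
    k = fit.n_params + 1  # +1 for the residual variance
    if n - k - 1 <= 0:
        return math.inf
    rss = max(fit.rss, 1e-300)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def aic_select(fits) -> FitResult:
    """Pick the fit minimising small-sample-corrected AIC (AICc).

    Ties are broken toward fewer phases.  A single candidate is returned
    unchanged.
    """
    fits = list(fits)
    if not fits:
        raise ValidationError("no fits supplied")
    if len(fits) == 1:
        return fits[0]
    for f in fits[1:]:
        if not fits[0].same_data(f):
            raise ValidationError("AIC comparison requires fits on identical data")
    scored = sorted(fits, key=lambda f: (_aicc(f), f.model.n_phases))
    return scored[0]


def time_integrated_activity(model: ExpModel, t_start_h: float = 0.0,
                             t_end_h: float = math.inf) -> float:
    """Closed-form integral of A(t) over [t_start, t_end], in MBq·h."""
    if t_start_h >= t_end_h:
        raise ValidationError("t_start must precede t_end")
    total = 0.0
    for a, lam in zip(model.amplitudes, model.decay_constants):
        upper = 0.0 if math.isinf(t_end_h) else math.exp(-lam * t_end_h)
        total += a / lam * (math.exp(-lam * t_start_h) - upper)
    return total


def coverage_fraction(model: ExpModel, t_first_h: float, t_last_h: float):
    """Fraction of Ã(0, inf) covered by the measured interval.

    Returns ``(fraction, meets_recommendation)`` where the recommendation is
    that measurements span at least 80 % of the total time-integrated
    activity.
    """
    if not 0 <= t_first_h < t_last_h:
        raise ValidationError("require 0 <= t_first < t_last")
    total = time_integrated_activity(model, 0.0, math.inf)
    inside = time_integrated_activity(model, t_first_h, t_last_h)
    frac = inside / total
    return frac, frac > 0.8 or math.isclose(frac, 0.8)
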