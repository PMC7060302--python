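"""Whole-body retention from external-counter (probe) measurements.

A ceiling-mounted Geiger or NaI counter at fixed geometry records the count
rate from the patient after every void.  The first, pre-void reading taken
immediately after administration is the baseline to which later readings are
normalised; multiplying the retained fraction by the net administered
activity yields a whole-body retention curve in absolute units (MBq).

Counting statistics are Poisson: a reading of N counts carries a relative
uncertainty 1/sqrt(N), so at least ~500 counts are needed to keep it below
5 %.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Readings closer together than this are replicates of one time point.
REPLICATE_WINDOW_H = 0.25

#: Counts below which a reading is flagged as statistically weak (>5 % noise).
MIN_RECOMMENDED_COUNTS = 500


@dataclass(frozen=True)
class ProbeReading:
    """One timed count measurement.

    Parameters
    ----------
    time_h : float
        Hours post administration (may be negative for a pre-administration
        background).
    counts : int
        Detected counts (>= 0).
    duration_s : float
        Acquisition live time in seconds (> 0).
    view : str
        ``"single"``, ``"AP"`` or ``"PA"``.
    is_background : bool
        True for room-background readings (no patient).
    """

    time_h: float
    counts: int
    duration_s: float
    view: str = "single"
    is_background: bool = False

    def __post_init__(self):
        if self.counts < 0:
            raise ValidationError(f"counts must be >= 0, got {self.counts}")
        if self.duration_s <= 0:
            raise ValidationError(f"duration_s must be > 0, got {self.duration_s}")
        if self.view not in ("single", "AP", "PA"):
            raise ValidationError(f"unknown view {self.view!r}")
        if not self.is_background and self.time_h < 0:
            raise ValidationError("patient readings require time_h >= 0")

    @property
    def raw_rate_cps(self) -> float:
        return self.counts / self.duration_s


@dataclass(frozen=True)
class NetRate:
    """Background-subtracted count rate with Poisson uncertainty."""

    rate_cps: float
    sigma_cps: float
    low_counts: bool = False
    valid: bool = True


@dataclass
class RetentionCurve:
    """Whole-body activity retention A(t).

    ``points`` is a list of ``(time_h, activity_MBq, sigma_MBq)`` with times
    strictly increasing; the earliest point equals the net administered
    activity by construction (retained fraction 1 at baseline).
    """

    points: list
    admin_activity_MBq: float
    baseline_rate_cps: float
    residual_rate_cps: float = 0.0
    provenance: dict = field(default_factory=dict)

    @property
    def times_h(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def activities_MBq(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    @property
    def sigmas_MBq(self) -> np.ndarray:
        return np.array([p[2] for p in self.points])

    @property
    def fractions(self) -> np.ndarray:
        return self.activities_MBq / self.admin_activity_MBq


def net_count_rate(counts: int, duration_s: float,
                   background_rate_cps: float = 0.0) -> NetRate:
    """Background-subtracted count rate from a single reading.

    sigma is the Poisson uncertainty of the gross counts, sqrt(N)/t; the
    background is treated as known.  A net rate below zero is flagged
    invalid (background exceeds signal), and counts at or below 500 raise a
    low-counts flag (relative noise above ~4.5 %).
    """
    if duration_s <= 0:
        raise ValidationError("duration_s must be > 0")
    if background_rate_cps < 0:
        raise ValidationError("background_rate_cps must be >= 0")
    if counts < 0:
        raise ValidationError("counts must be >= 0")
    rate = counts / duration_s - background_rate_cps
    sigma = math.sqrt(counts) / duration_s
    low = counts <= MIN_RECOMMENDED_COUNTS
    valid = rate >= 0
    if not valid:
        warnings.warn("net count rate negative: background exceeds signal",
                      stacklevel=2)
    return NetRate(rate_cps=rate, sigma_cps=sigma, low_counts=low, valid=valid)


def min_counts_for_precision(relative_noise: float) -> int:
    """Smallest count total N with Poisson relative noise 1/sqrt(N) <= target.

    E.g. 5 % noise requires 400 counts; the conventional ">500 counts" rule
    corresponds to about 4.5 %.
    """
    if not 0 < relative_noise < 1:
        raise ValidationError("relative_noise must lie in (0, 1)")
    n = math.ceil(1.0 / relative_noise ** 2)
    # ceil can land one short when 1/rel^2 is an exact integer boundary
    while 1.0 / math.sqrt(n) > relative_noise:
        n += 1
    return n


def geometric_mean_rate(rate_ap_cps: float, rate_pa_cps: float) -> float:
    """Geometric mean of anterior-posterior and posterior-anterior rates."""
    if rate_ap_cps <= 0 or rate_pa_cps <= 0:
        raise ValidationError("geometric mean requires strictly positive rates")
    return math.sqrt(rate_ap_cps * rate_pa_cps)


def _background_rate_for(time_h, backgrounds):
    """Most recent background at or before ``time_h``; falls back to the
    earliest (pre-administration) background."""
    prior = [b for b in backgrounds if b.time_h <= time_h]
    chosen = max(prior, key=lambda b: b.time_h) if prior else \
        min(backgrounds, key=lambda b: b.time_h)
    return chosen.raw_rate_cps, math.sqrt(chosen.counts) / chosen.duration_s


def _cluster_by_time(readings, window_h=REPLICATE_WINDOW_H):
    """Group readings into replicate clusters: each cluster spans at most
    ``window_h`` from its first reading."""
    clusters = []
    for r in sorted(readings, key=lambda r: r.time_h):
        if clusters and r.time_h - clusters[-1][0].time_h <= window_h:
            clusters[-1].append(r)
        else:
            clusters.append([r])
    return clusters


def _combine_cluster(cluster, backgrounds):
    """Net rate for one time point: replicates averaged per view, AP/PA
    combined by geometric mean when both present."""
    t = float(np.mean([r.time_h for r in cluster]))
    by_view = {}
    for r in cluster:
        bkg, _ = _background_rate_for(r.time_h, backgrounds)
        nr = net_count_rate(r.counts, r.duration_s, bkg)
        by_view.setdefault(r.view, []).append(nr)

    def _avg(rates):
        k = len(rates)
        rate = float(np.mean([x.rate_cps for x in rates]))
        sigma = math.sqrt(sum(x.sigma_cps ** 2 for x in rates)) / k
        return rate, sigma

    if "AP" in by_view and "PA" in by_view:
        rate_ap, sig_ap = _avg(by_view["AP"])
        rate_pa, sig_pa = _avg(by_view["PA"])
        rate = geometric_mean_rate(rate_ap, rate_pa)
        # first-order propagation through sqrt(ap*pa)
        sigma = 0.5 * rate * math.sqrt((sig_ap / rate_ap) ** 2
                                       + (sig_pa / rate_pa) ** 2)
        mode = "geometric_mean"
    else:
        all_rates = [x for v in by_view.values() for x in v]
        rate, sigma = _avg(all_rates)
        mode = "single_view"
    return t, rate, sigma, mode


def build_retention_curve(readings, backgrounds, admin_activity_MBq,
                          residual_rate_cps=0.0) -> RetentionCurve:
    """Assemble the whole-body retention curve from probe readings.

    The first (earliest, pre-void) patient reading defines the baseline net
    rate corresponding to the full administered activity.  Each later point
    is normalised as

        A(t) = A_admin * (net_rate(t) - residual) / (baseline - residual)

    where ``residual_rate_cps`` is the pre-administration patient rate left
    over from a previous therapy cycle (zero for a first treatment).
    Replicate readings within 15 min are averaged before normalisation and
    AP/PA pairs are combined by geometric mean.
    """
    patient = [r for r in readings if not r.is_background]
    bkg = list(backgrounds) + [r for r in readings if r.is_background]
    if not patient:
        raise ValidationError("no patient readings supplied")
    if not bkg:
        raise ValidationError("at least one background reading is required")
    if admin_activity_MBq <= 0:
        raise ValidationError("admin_activity_MBq must be > 0")

    clusters = _cluster_by_time(patient)
    combined = [_combine_cluster(c, bkg) for c in clusters]

    t0, baseline, sigma0, mode0 = combined[0]
    denom = baseline - residual_rate_cps
    if denom <= 0:
        raise ValidationError(
            "baseline (pre-void) net rate must exceed the residual rate; "
            "is the first reading missing?")

    points = []
    view_modes = []
    warnings_list = []
    for i, (t, rate, sigma, mode) in enumerate(combined):
        if i == 0:
            frac, fsig = 1.0, sigma0 / denom
        else:
            frac = (rate - residual_rate_cps) / denom
            fsig = sigma / denom
            if rate > baseline:
                msg = (f"net rate at t={t:.2f} h exceeds baseline; geometry "
                       "or contamination suspect")
                warnings.warn(msg, stacklevel=2)
                warnings_list.append(msg)
        frac = max(frac, 0.0)
        points.append((t, admin_activity_MBq * frac, admin_activity_MBq * fsig))
        view_modes.append(mode)

    return RetentionCurve(
        points=points,
        admin_activity_MBq=admin_activity_MBq,
        baseline_rate_cps=baseline,
        residual_rate_cps=residual_rate_cps,
        provenance={"view_modes": view_modes, "warnings": warnings_list,
                    "n_backgrounds": len(bkg)},
    )
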