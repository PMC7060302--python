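"""Seeded synthetic-data generators with recorded ground truth.

Every pipeline stage can be exercised without external data: probe count
series (Poisson counting of a multi-exponential retention), dead-time
count-rate series (paralysable model, optionally two camera modes),
blurred sphere phantoms (partial-volume behaviour) and lesion/organ
time-activity curves.  Each generator returns the dataset together with a
``SimTruth`` capturing all generating parameters, and is bit-reproducible
for a fixed seed.

Noise models: Poisson for detected counts, multiplicative Gaussian for
count rates — the simplest models consistent with counting statistics and
rate-meter behaviour.  The sphere-phantom PSF is an isotropic Gaussian, a
stand-in for the high-energy-collimator system response (default FWHM
15 mm).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .spect import VoxelImage

#: Default isotropic PSF FWHM (mm) emulating a 131I HEGP system response.
DEFAULT_PSF_FWHM_MM = 15.0

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class SimTruth:
    """Ground-truth record for one generated dataset."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))
        return json.dumps(dataclasses.asdict(self), default=_default, indent=2)


def gen_probe_series(A0_MBq: float, phases, schedule_h,
                     counter_sensitivity_cps_per_MBq: float,
                     background_cps: float = 0.5,
                     duration_s: float = 60.0,
                     seed: int = 0):
    """Poisson probe-count series from a multi-exponential retention curve.

    ``phases`` is a list of ``(amplitude_MBq, lambda_per_h)`` whose
    amplitudes must sum to ``A0_MBq``.  The series includes a pre-void
    baseline reading at t = 0 and a pre-administration background reading.

    Returns ``(DataFrame, SimTruth)`` with columns time_h, counts,
    duration_s, view, is_background.
    """
    amps = np.array([p[0] for p in phases], dtype=float)
    lams = np.array([p[1] for p in phases], dtype=float)
    if np.any(lams <= 0):
        raise ValidationError("decay constants must be > 0")
    if not math.isclose(amps.sum(), A0_MBq, rel_tol=1e-9):
        raise ValidationError("phase amplitudes must sum to A0")
    rng = np.random.default_rng(seed)

    times = np.concatenate([[0.0], np.asarray(schedule_h, dtype=float)])
    times = np.unique(times)
    rows = [{"time_h": -1.0,
             "counts": int(rng.poisson(background_cps * 600.0)),
             "duration_s": 600.0, "view": "single", "is_background": True}]
    for t in times:
        activity = float((amps * np.exp(-lams * t)).sum())
        mean_counts = (activity * counter_sensitivity_cps_per_MBq
                       + background_cps) * duration_s
        rows.append({"time_h": float(t),
                     "counts": int(rng.poisson(mean_counts)),
                     "duration_s": duration_s, "view": "single",
                     "is_background": False})
    df = pd.DataFrame(rows)
    truth = SimTruth(generator="gen_probe_series", seed=seed, params={
        "A0_MBq": A0_MBq, "amplitudes_MBq": amps, "lambdas_per_h": lams,
        "schedule_h": np.asarray(schedule_h, dtype=float),
        "sensitivity_cps_per_MBq": counter_sensitivity_cps_per_MBq,
        "background_cps": background_cps, "duration_s": duration_s})
    return df, truth


def gen_deadtime_series(activity_steps_MBq, sensitivity_cps_per_MBq: float,
                        mode_taus_s, mode_switch_cps: float = None,
                        noise_cv: float = 0.0, seed: int = 0):
    """Observed count-rate series of a paralysable camera vs source activity.

    ``mode_taus_s`` is a single tau or a ``(low_mode_tau, high_mode_tau)``
    pair with ``mode_switch_cps`` the incident-rate threshold where the
    high-count-rate mode takes over.  Rates carry multiplicative Gaussian
    noise of coefficient of variation ``noise_cv``.

    Returns ``(DataFrame, SimTruth)`` with columns activity_MBq,
    observed_cps.
    """
    A = np.asarray(activity_steps_MBq, dtype=float)
    if np.any(np.diff(A) <= 0):
        raise ValidationError("activity steps must be strictly increasing")
    taus = np.atleast_1d(np.asarray(mode_taus_s, dtype=float))
    if np.any(taus < 0):
        raise ValidationError("tau must be >= 0")
    if taus.size > 1 and mode_switch_cps is None:
        raise ValidationError("two modes require mode_switch_cps")
    rng = np.random.default_rng(seed)

    inc = sensitivity_cps_per_MBq * A
    tau_used = np.full_like(inc, taus[0])
    if taus.size > 1:
        tau_used[inc > mode_switch_cps] = taus[1]
    obs = inc * np.exp(-inc * tau_used)
    if noise_cv > 0:
        obs = obs * (1.0 + noise_cv * rng.standard_normal(obs.shape))
    df = pd.DataFrame({"activity_MBq": A, "observed_cps": obs})
    truth = SimTruth(generator="gen_deadtime_series", seed=seed, params={
        "sensitivity_cps_per_MBq": sensitivity_cps_per_MBq,
        "mode_taus_s": taus, "mode_switch_cps": mode_switch_cps,
        "noise_cv": noise_cv, "incident_cps": inc})
    return df, truth


def _rasterise_sphere(shape, voxel_mm, center_mm, radius_mm, subdiv=4):
    """Partial-voxel-weighted indicator of a sphere on a voxel grid."""
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    coords = np.stack([(zz + 0.5) * voxel_mm[0], (yy + 0.5) * voxel_mm[1],
                       (xx + 0.5) * voxel_mm[2]])
    dist = np.sqrt(((coords - np.asarray(center_mm)[:, None, None, None]) ** 2
                    ).sum(axis=0))
    half_diag = 0.5 * math.sqrt(sum(v ** 2 for v in voxel_mm))
    weights = np.zeros(shape)
    weights[dist <= radius_mm - half_diag] = 1.0
    edge = np.argwhere((dist > radius_mm - half_diag)
                       & (dist < radius_mm + half_diag))
    if len(edge):
        offs = (np.stack(np.meshgrid(*[np.arange(subdiv)] * 3,
                                     indexing="ij"), axis=-1)
                .reshape(-1, 3) + 0.5) / subdiv  # sub-voxel centres in [0,1)
        vox = np.asarray(voxel_mm)
        sub = (edge[:, None, :] + offs[None, :, :]) * vox[None, None, :]
        d = np.sqrt(((sub - np.asarray(center_mm)[None, None, :]) ** 2
                     ).sum(axis=-1))
        weights[tuple(edge.T)] = (d <= radius_mm).mean(axis=1)
    return weights


def gen_sphere_phantom(grid_shape, voxel_mm, spheres,
                       background_conc_cps_per_ml: float = 0.0,
                       psf_fwhm_mm: float = DEFAULT_PSF_FWHM_MM,
                       poisson_noise: bool = False, seed: int = 0):
    """Voxelised sphere phantom blurred with a Gaussian PSF.

    ``spheres`` is a list of dicts with keys ``center_mm`` (3-tuple),
    ``diameter_mm`` and ``conc_cps_per_ml`` (count-rate concentration above
    background).  Overlapping spheres are rejected.  Truth records, per
    sphere, its exact volume, total emitted rate, and the rate remaining
    inside the true sphere mask after blurring (the enclosed-count fraction
    drives the recovery coefficient).

    Returns ``(VoxelImage, sphere_masks, SimTruth)``.
    """
    from scipy import ndimage

    if psf_fwhm_mm < 0:
        raise ValidationError("PSF FWHM must be >= 0")
    centers = [np.asarray(s["center_mm"], dtype=float) for s in spheres]
    radii = [0.5 * s["diameter_mm"] for s in spheres]
    extent = np.asarray(grid_shape) * np.asarray(voxel_mm)
    for c, r in zip(centers, radii):
        if np.any(c - r < 0) or np.any(c + r > extent):
            raise ValidationError("sphere extends outside the grid")
    for i in range(len(spheres)):
        for j in range(i + 1, len(spheres)):
            if np.linalg.norm(centers[i] - centers[j]) < radii[i] + radii[j]:
                raise ValidationError(f"spheres {i} and {j} overlap")

    rng = np.random.default_rng(seed)
    voxel_ml = float(np.prod(voxel_mm)) / 1000.0
    data = np.full(grid_shape, background_conc_cps_per_ml * voxel_ml)
    masks, truths = [], []
    weight_maps = []
    for s, c, r in zip(spheres, centers, radii):
        w = _rasterise_sphere(grid_shape, voxel_mm, c, r)
        data += w * s["conc_cps_per_ml"] * voxel_ml
        weight_maps.append(w)
        masks.append(w >= 0.5)

    if psf_fwhm_mm > 0:
        sigma_vox = [psf_fwhm_mm * _FWHM_TO_SIGMA / v for v in voxel_mm]
        blurred = ndimage.gaussian_filter(data, sigma_vox, mode="constant")
    else:
        blurred = data.copy()

    for s, w, m, r in zip(spheres, weight_maps, masks, radii):
        true_volume_ml = 4.0 / 3.0 * math.pi * r ** 3 / 1000.0
        total_rate = float((w * s["conc_cps_per_ml"] * voxel_ml).sum())
        bkg_in_mask = background_conc_cps_per_ml * voxel_ml * m.sum()
        enclosed = float(blurred[m].sum() - bkg_in_mask)
        truths.append({"true_volume_ml": true_volume_ml,
                       "raster_volume_ml": float(w.sum()) * voxel_ml,
                       "total_rate_cps": total_rate,
                       "enclosed_rate_cps": enclosed,
                       "enclosed_fraction": enclosed / total_rate
                       if total_rate else 0.0})

    if poisson_noise:
        blurred = rng.poisson(np.clip(blurred, 0, None)).astype(float)

    image = VoxelImage(data=blurred, voxel_mm=tuple(voxel_mm), unit="cps")
    truth = SimTruth(generator="gen_sphere_phantom", seed=seed, params={
        "voxel_mm": list(voxel_mm), "psf_fwhm_mm": psf_fwhm_mm,
        "background_conc_cps_per_ml": background_conc_cps_per_ml,
        "poisson_noise": poisson_noise, "spheres": truths})
    return image, masks, truth


def gen_lesion_tac(A0_MBq: float, T_eff_h: float, scan_times_h,
                   noise_cv: float = 0.0, seed: int = 0):
    """Mono-exponential lesion/organ time-activity samples.

    Activities at the scan times carry multiplicative Gaussian noise of
    coefficient of variation ``noise_cv``.  Returns ``(DataFrame, SimTruth)``
    with columns time_h, activity_MBq, sigma_MBq.
    """
    t = np.asarray(scan_times_h, dtype=float)
    if np.any(t <= 0):
        raise ValidationError("scan times must be > 0")
    if T_eff_h <= 0 or A0_MBq <= 0:
        raise ValidationError("A0 and T_eff must be > 0")
    rng = np.random.default_rng(seed)
    lam = math.log(2.0) / T_eff_h
    activity = A0_MBq * np.exp(-lam * t)
    noisy = activity * (1.0 + noise_cv * rng.standard_normal(t.shape)) \
        if noise_cv > 0 else activity.copy()
    df = pd.DataFrame({"time_h": t, "activity_MBq": noisy,
                       "sigma_MBq": noise_cv * activity})
    truth = SimTruth(generator="gen_lesion_tac", seed=seed, params={
        "A0_MBq": A0_MBq, "T_eff_h": T_eff_h, "lambda_per_h": lam,
        "noise_cv": noise_cv})
    return df, truth
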