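"""SPECT VOI quantification: scatter, attenuation, segmentation, activity.

Reconstructed 131I SPECT images are only count-rate maps; converting a
volume-of-interest (VOI) count rate into activity requires triple-energy-
window (TEW) scatter correction of the projections, attenuation correction
(first-order Chang when no CT map is available), a dead-time factor, the
camera calibration factor Q, and a partial-volume recovery coefficient:

    A_v(t) = rate_v(t) / (Q * R(v)) * DTF
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError


@dataclass(frozen=True)
class EnergyWindowSet:
    """Photopeak window plus the two adjacent narrow scatter windows.

    Each window is ``(center_keV, width_keV)``.  For 131I the photopeak is
    364 keV with a 15-20 % width and 6 % scatter windows either side.
    """

    peak: tuple
    lower: tuple
    upper: tuple

    def __post_init__(self):
        for name, (c, w) in (("peak", self.peak), ("lower", self.lower),
                             ("upper", self.upper)):
            if w <= 0:
                raise ValidationError(f"{name} window width must be > 0")
        if not self.lower[0] < self.peak[0] < self.upper[0]:
            raise ValidationError("windows must be ordered lower < peak < upper")
        # non-overlap: window edges must not cross
        if self.lower[0] + self.lower[1] / 2 > self.peak[0] - self.peak[1] / 2 + 1e-9:
            raise ValidationError("lower window overlaps the photopeak window")
        if self.upper[0] - self.upper[1] / 2 < self.peak[0] + self.peak[1] / 2 - 1e-9:
            raise ValidationError("upper window overlaps the photopeak window")


def i131_windows(peak_fraction: float = 0.20,
                 scatter_fraction: float = 0.06) -> EnergyWindowSet:
    """Standard 131I TEW windows around the 364-keV photopeak."""
    peak_c = 364.0
    wp = peak_fraction * peak_c
    ws = scatter_fraction * peak_c
    return EnergyWindowSet(peak=(peak_c, wp),
                           lower=(peak_c - wp / 2 - ws / 2, ws),
                           upper=(peak_c + wp / 2 + ws / 2, ws))


@dataclass
class VoxelImage:
    """A 3-D voxel array with physical voxel sizes and provenance.

    ``unit`` tags the voxel values ("counts" or "cps");
    ``corrections_applied`` prevents double-applying scatter/attenuation/
    dead-time corrections.
    """

    data: np.ndarray
    voxel_mm: tuple
    unit: str = "cps"
    frame_duration_s: float = None
    corrections_applied: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("VoxelImage requires a 3-D array")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValidationError("voxel sizes must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("voxel values must be finite")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_mm)) / 1000.0


@dataclass
class VoiMeasurement:
    """One VOI count-rate measurement converted to activity."""

    scan_time_h: float
    count_rate_cps: float
    voi_volume_ml: float
    dtf: float
    recovery: float
    activity_MBq: float


def tew_correct(C_peak, C_lower, C_upper, windows: EnergyWindowSet):
    """Triple-energy-window scatter correction, element-wise.

    Scatter in the photopeak window is estimated as the trapezoid spanned by
    the count densities of the two flanking narrow windows:

        C_sc = C_peak - (W_peak/2) * (C1/W1 + C2/W2),

    clamped at zero (counts cannot be negative).
    """
    cp = np.asarray(C_peak, dtype=float)
    c1 = np.asarray(C_lower, dtype=float)
    c2 = np.asarray(C_upper, dtype=float)
    if np.any(cp < 0) or np.any(c1 < 0) or np.any(c2 < 0):
        raise ValidationError("window counts must be >= 0")
    wp = windows.peak[1]
    w1 = windows.lower[1]
    w2 = windows.upper[1]
    out = cp - (wp / 2.0) * (c1 / w1 + c2 / w2)
    out = np.clip(out, 0.0, None)
    return float(out) if np.isscalar(C_peak) else out


def chang_correction_factors(mask: np.ndarray, voxel_mm, mu_per_cm: float,
                             n_angles: int = 64, points=None,
                             step_fraction: float = 0.5) -> np.ndarray:
    """First-order Chang correction factors for voxels of a body mask.

    For each voxel the in-mask path length d_m to the boundary is traced
    along ``n_angles`` equally spaced in-plane rays (bilinear mask sampling
    at half-voxel steps); the factor is 1 / mean_m(exp(-mu * d_m)).

    ``points`` restricts evaluation to an (N, 3) array of voxel indices
    (default: every in-mask voxel).  Returns factors aligned with ``points``
    or, when points is None, a full image of factors (1.0 outside the mask).
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValidationError("mask must be 3-D")
    if mu_per_cm < 0:
        raise ValidationError("mu must be >= 0")
    maskf = mask.astype(float)
    dy, dx = float(voxel_mm[1]), float(voxel_mm[2])
    step_mm = step_fraction * min(dy, dx)
    ny, nx = mask.shape[1], mask.shape[2]
    diag_mm = math.hypot(ny * dy, nx * dx)
    n_steps = int(math.ceil(diag_mm / step_mm)) + 2

    full_output = points is None
    if full_output:
        points = np.argwhere(mask)
    else:
        points = np.asarray(points)
    factors = np.ones(len(points))
    if mu_per_cm == 0 or len(points) == 0:
        if full_output:
            out = np.ones(mask.shape)
            return out
        return factors

    angles = np.arange(n_angles) * (2 * math.pi / n_angles)
    s = step_mm * np.arange(1, n_steps + 1)  # radial sample distances, mm

    for z in np.unique(points[:, 0]):
        sel = points[:, 0] == z
        pyx = points[sel, 1:].astype(float)  # (N, 2) voxel indices
        transmission = np.zeros(len(pyx))
        plane = maskf[z]
        for th in angles:
            # physical direction -> voxel-index increments per mm
            vy = math.sin(th) / dy
            vx = math.cos(th) / dx
            yy = pyx[:, 0, None] + s[None, :] * vy
            xx = pyx[:, 1, None] + s[None, :] * vx
            vals = ndimage.map_coordinates(
                plane, [yy.ravel(), xx.ravel()], order=1, mode="constant",
                cval=0.0).reshape(yy.shape)
            outside = vals < 0.5
            first_out = np.where(outside.any(axis=1),
                                 outside.argmax(axis=1), n_steps)
            # boundary lies between samples first_out-1 and first_out
            d_cm = ((first_out + 0.5) * step_mm) / 10.0
            transmission += np.exp(-mu_per_cm * d_cm)
        factors[sel] = n_angles / transmission

    if full_output:
        out = np.ones(mask.shape)
        out[tuple(points.T)] = factors
        return out
    return factors


def chang_attenuation_correct(image: VoxelImage, body_mask: np.ndarray,
                              mu_per_cm: float = 0.11,
                              n_angles: int = 64) -> VoxelImage:
    """Apply first-order Chang attenuation correction inside the body mask.

    Voxels outside the mask are untouched; mu = 0 is the identity.  The
    default mu of 0.11 /cm is the attenuation coefficient of 364-keV photons
    in water.
    """
    if body_mask.shape != image.data.shape:
        raise ValidationError("mask and image grids differ")
    if "attenuation" in image.corrections_applied:
        raise ValidationError("attenuation correction already applied")
    factors = chang_correction_factors(body_mask, image.voxel_mm, mu_per_cm,
                                       n_angles=n_angles)
    return VoxelImage(data=image.data * factors, voxel_mm=image.voxel_mm,
                      unit=image.unit, frame_duration_s=image.frame_duration_s,
                      corrections_applied=image.corrections_applied
                      + ["attenuation"])


def voi_count_rate(image: VoxelImage, mask: np.ndarray):
    """Total count rate and volume of a VOI.

    Returns ``(rate_cps, volume_ml)``.
    """
    if image.unit != "cps":
        raise ValidationError("image must be in cps units")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.data.shape:
        raise ValidationError("mask and image grids differ")
    n = int(mask.sum())
    if n == 0:
        raise ValidationError("empty VOI mask")
    return float(image.data[mask].sum()), n * image.voxel_volume_ml


def _component_at(binary, seed):
    labels, _ = ndimage.label(binary)
    lab = labels[tuple(seed)]
    if lab == 0:
        return None
    return labels == lab


def adaptive_threshold_mask(image: VoxelImage, target_volume_ml: float,
                            seed_point) -> np.ndarray:
    """Threshold-based VOI of a target volume around a seed voxel.

    Bisects the threshold (as a fraction of the local maximum — the maximum
    of the connected object containing the seed) until the connected
    component containing the seed matches the target volume within half a
    voxel, or 50 bisection steps are exhausted (nearest volume returned).
    """
    vox_ml = image.voxel_volume_ml
    if target_volume_ml <= vox_ml:
        raise ValidationError("target volume must exceed one voxel")
    seed = tuple(int(i) for i in seed_point)
    data = image.data
    if data[seed] <= 0:
        raise ValidationError("seed voxel has no signal (background?)")

    base = _component_at(data > 0, seed)
    if base is None:
        raise ValidationError("seed voxel not inside any object")
    local_max = float(data[base].max())

    def volume_at(frac):
        comp = _component_at(data >= frac * local_max, seed)
        if comp is None:
            return 0.0, None
        return float(comp.sum()) * vox_ml, comp

    lo, hi = 1e-6, 1.0
    vol_lo, mask_lo = volume_at(lo)
    if target_volume_ml > vol_lo + vox_ml / 2:
        raise ValidationError(
            f"target {target_volume_ml:.1f} ml unreachable: object spans at "
            f"most {vol_lo:.1f} ml at any threshold")

    best_mask, best_err = mask_lo, abs(vol_lo - target_volume_ml)
    if best_err <= vox_ml / 2:
        return best_mask
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        vol, comp = volume_at(mid)
        err = abs(vol - target_volume_ml)
        if comp is not None and err < best_err:
            best_mask, best_err = comp, err
        if err <= vox_ml / 2 and comp is not None:
            return comp
        if vol > target_volume_ml:
            lo = mid  # need a higher threshold to shrink
        else:
            hi = mid
    return best_mask


def block27_extrema(image: VoxelImage, mask: np.ndarray) -> dict:
    """Extrema of 3x3x3-block mean values over blocks fully inside a mask.

    Blocks of 27 voxels are less noise-prone than single-voxel extrema when
    locating maximum/minimum-uptake sub-volumes.  Returns the max and min
    block means and the centre indices of the corresponding blocks.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.data.shape:
        raise ValidationError("mask and image grids differ")
    interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3, 3)))
    # uniform_filter at the boundary uses reflected values; exclude by masking
    interior[0, :, :] = interior[-1, :, :] = False
    interior[:, 0, :] = interior[:, -1, :] = False
    interior[:, :, 0] = interior[:, :, -1] = False
    if not interior.any():
        raise ValidationError("mask admits no fully interior 3x3x3 block")
    means = ndimage.uniform_filter(image.data, size=3, mode="constant")
    vals = means[interior]
    centers = np.argwhere(interior)
    imax, imin = int(np.argmax(vals)), int(np.argmin(vals))
    return {"max_block_mean": float(vals[imax]),
            "min_block_mean": float(vals[imin]),
            "max_center": tuple(centers[imax]),
            "min_center": tuple(centers[imin])}


def average_projection_rate(projection_counts, frame_duration_s):
    """Mean count rate over a projection set: mean_i(counts_i / duration_i)."""
    counts = np.asarray(projection_counts, dtype=float)
    if counts.ndim > 1:  # per-view images: total counts per view
        counts = counts.reshape(counts.shape[0], -1).sum(axis=1)
    durations = np.broadcast_to(
        np.asarray(frame_duration_s, dtype=float), counts.shape)
    if np.any(durations <= 0):
        raise ValidationError("frame durations must be > 0")
    return float(np.mean(counts / durations))


def activity_from_voi(count_rate_cps: float, Q: float, R: float,
                      DTF: float = 1.0) -> float:
    """VOI activity A = rate / (Q * R) * DTF, in MBq."""
    if Q <= 0:
        raise ValidationError("Q must be > 0")
    if R <= 0:
        raise ValidationError("recovery coefficient must be > 0")
    if DTF < 1.0:
        raise ValidationError("DTF must be >= 1")
    if count_rate_cps < 0:
        raise ValidationError("count rate must be >= 0")
    return count_rate_cps / (Q * R) * DTF
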