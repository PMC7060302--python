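"""File readers/writers, run configuration and report provenance.

CSV schemas (UTF-8, comma-separated, header row, dot decimals):

* probe:     time_iso, counts, duration_s, view, is_background
             (+ YAML sidecar with administered activity, datetime, mass)
* TAC:       time_h, activity_MBq, sigma_MBq
* dead time: activity_MBq, observed_cps[, datetime]
* recovery:  insert_volume_ml, voi_rate_cps, true_activity_MBq
* VOI:       scan_time_h, rate_cps, volume_ml, DTF, R[, activity_MBq]

Voxel images and masks travel as NIfTI-1 with mm voxel sizes.  Reports are
JSON and embed the tool version, a config hash and SHA-256 hashes of every
input file so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .probe import ProbeReading
from .spect import VoxelImage


# ---------------------------------------------------------------- config --

@dataclass
class RunConfig:
    """Structured run configuration (patient, protocol, camera)."""

    patient_mass_kg: float = None
    patient_mass_sigma_kg: float = 0.0
    administered_MBq: float = None
    admin_datetime: str = None
    target_wb_dose_Gy: float = 4.0
    n_fractions: int = 2
    alpha: float = 0.05
    camera_Q_cps_per_MBq: float = None
    camera_taus_s: list = field(default_factory=list)
    camera_mode_switch_cps: float = None
    recovery_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        patient = raw.get("patient", {})
        protocol = raw.get("protocol", {})
        camera = raw.get("camera", {})
        cfg = cls(
            patient_mass_kg=patient.get("mass_kg"),
            patient_mass_sigma_kg=patient.get("mass_sigma_kg", 0.0),
            administered_MBq=patient.get("administered_MBq"),
            admin_datetime=patient.get("admin_datetime"),
            target_wb_dose_Gy=protocol.get("target_wb_dose_Gy", 4.0),
            n_fractions=protocol.get("n_fractions", 2),
            alpha=protocol.get("alpha", 0.05),
            camera_Q_cps_per_MBq=camera.get("Q_cps_per_MBq"),
            camera_taus_s=camera.get("taus_s", []),
            camera_mode_switch_cps=camera.get("mode_switch_cps"),
            recovery_params=camera.get("recovery", {}),
        )
        if cfg.patient_mass_kg is not None and cfg.patient_mass_kg <= 0:
            raise ValidationError("patient mass must be > 0")
        if cfg.n_fractions < 1:
            raise ValidationError("n_fractions must be >= 1")
        return cfg

    def hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ------------------------------------------------------------------- CSV --

def read_probe_csv(path, sidecar_path=None):
    """Read a probe CSV (+ optional YAML sidecar with admin metadata).

    Returns ``(readings, metadata)``; times are converted to hours post the
    administration datetime from the sidecar, or taken from a ``time_h``
    column when no sidecar/ISO column is present.
    """
    df = pd.read_csv(path)
    meta = {}
    if sidecar_path is not None:
        meta = yaml.safe_load(Path(sidecar_path).read_text()) or {}
    if "time_h" in df.columns:
        times = df["time_h"].astype(float)
    elif "time_iso" in df.columns:
        if "admin_datetime" not in meta:
            raise ValidationError(
                "time_iso column requires admin_datetime in the sidecar")
        t0 = pd.Timestamp(meta["admin_datetime"])
        times = (pd.to_datetime(df["time_iso"]) - t0) / pd.Timedelta(hours=1)
    else:
        raise ValidationError("probe CSV needs a time_h or time_iso column")
    readings = [
        ProbeReading(time_h=float(t), counts=int(r.counts),
                     duration_s=float(r.duration_s),
                     view=getattr(r, "view", "single"),
                     is_background=bool(r.is_background))
        for t, r in zip(times, df.itertuples(index=False))
    ]
    return readings, meta


def read_tac_csv(path):
    """Read a TAC CSV into (times_h, activities_MBq, sigmas_MBq or None)."""
    df = pd.read_csv(path)
    for col in ("time_h", "activity_MBq"):
        if col not in df.columns:
            raise ValidationError(f"TAC CSV missing column {col!r}")
    sig = df["sigma_MBq"].to_numpy(float) if "sigma_MBq" in df.columns else None
    return df["time_h"].to_numpy(float), df["activity_MBq"].to_numpy(float), sig


def read_deadtime_csv(path):
    df = pd.read_csv(path)
    for col in ("activity_MBq", "observed_cps"):
        if col not in df.columns:
            raise ValidationError(f"dead-time CSV missing column {col!r}")
    return df["activity_MBq"].to_numpy(float), df["observed_cps"].to_numpy(float)


def read_recovery_csv(path):
    df = pd.read_csv(path)
    for col in ("insert_volume_ml", "voi_rate_cps", "true_activity_MBq"):
        if col not in df.columns:
            raise ValidationError(f"recovery CSV missing column {col!r}")
    return (df["insert_volume_ml"].to_numpy(float),
            df["voi_rate_cps"].to_numpy(float),
            df["true_activity_MBq"].to_numpy(float))


def read_voi_csv(path):
    df = pd.read_csv(path)
    for col in ("scan_time_h", "rate_cps"):
        if col not in df.columns:
            raise ValidationError(f"VOI CSV missing column {col!r}")
    return df


# ----------------------------------------------------------------- NIfTI --

def read_voxel_image(path, unit="cps", frame_duration_s=None) -> VoxelImage:
    import nibabel as nib
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    voxel_mm = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelImage(data=data, voxel_mm=voxel_mm, unit=unit,
                      frame_duration_s=frame_duration_s)


def write_voxel_image(image: VoxelImage, path) -> None:
    import nibabel as nib
    affine = np.diag(list(image.voxel_mm) + [1.0])
    nib.save(nib.Nifti1Image(image.data.astype(np.float32), affine), str(path))


def read_mask(path) -> np.ndarray:
    import nibabel as nib
    return np.asanyarray(nib.load(str(path)).dataobj) > 0.5


# --------------------------------------------------------------- reports --

def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def make_report(kind: str, payload: dict, inputs=(), config: RunConfig = None,
                seed=None) -> dict:
    """Wrap a result payload with reproducibility provenance."""
    report = {
        "report": kind,
        "tool": "mibgdose",
        "version": __version__,
        "generated": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "inputs": {str(p): file_sha256(p) for p in inputs},
    }
    if config is not None:
        report["config_hash"] = config.hash()
    if seed is not None:
        report["seed"] = seed
    report.update(payload)
    return report


def write_report(report: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(report, indent=2, default=_default))
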