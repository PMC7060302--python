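import numpy as np
import pytest

from mibgdose import synth


@pytest.fixture(scope="session")
def deadtime_design():
    """Canonical dead-time characterisation design: 25 geometric activity
    steps driving the camera past its paralysable count-rate maximum
    (NEMA-style count-rate series)."""
    return {
        "activities_MBq": np.geomspace(2.0, 250.0, 25),
        "sensitivity_cps_per_MBq": 170.0,
        "tau_s": 12.8e-6,
    }


@pytest.fixture(scope="session")
def sphere_phantom():
    """A single blurred sphere (~42.8 ml, 15-mm FWHM PSF) on a 4.67-mm grid."""
    vox = 4.67
    shape = (48, 48, 48)
    center = tuple(0.5 * n * vox for n in shape)
    image, masks, truth = synth.gen_sphere_phantom(
        shape, (vox,) * 3,
        [{"center_mm": center, "diameter_mm": 43.4, "conc_cps_per_ml": 50.0}],
        psf_fwhm_mm=15.0, seed=7)
    return image, masks[0], truth


@pytest.fixture(scope="session")
def cylinder_mask():
    """Single-slice circular body mask of radius 10 cm, 5-mm voxels, with the
    exact centre on a voxel (odd grid)."""
    n, vox, r_cm = 49, 5.0, 10.0
    cy = cx = n // 2
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    mask = (((yy - cy) ** 2 + (xx - cx) ** 2) * (vox / 10.0) ** 2
            <= r_cm ** 2)[None, :, :]
    return mask, (vox, vox, vox), (0, cy, cx), r_cm
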