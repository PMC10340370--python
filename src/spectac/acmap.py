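"""CT to attenuation-map conversion.

Converts CT volumes in Hounsfield units to linear attenuation coefficient
maps (cm^-1) at the 140 keV photopeak of 99mTc using the standard bilinear
transform: below the water breakpoint attenuation scales with density
relative to water, above it a shallower bone slope applies.  Maps are then
smoothed to match the spatial resolution of the reconstructed emission
images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Role, Volume3

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class BilinearParams:
    """Bilinear HU -> mu calibration at 140 keV.

    mu_water 0.1537 cm^-1 is the linear attenuation coefficient of water at
    140 keV; the bone slope (cm^-1 per HU above the breakpoint) is a typical
    value for this energy.  Both are configuration, not fitted values.
    """

    mu_water_cm1: float = 0.1537
    bone_slope_cm1_per_hu: float = 7.0e-5
    breakpoint_hu: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_water_cm1 <= 0:
            raise ValueError("mu_water must be positive")
        if self.bone_slope_cm1_per_hu < 0:
            raise ValueError("bone slope must be nonnegative")


def hu_to_mu(ct: Volume3, params: BilinearParams = BilinearParams()) -> Volume3:
    """Bilinear conversion of a CT volume to attenuation coefficients.

    For HU <= breakpoint: ``mu = mu_water * (HU + 1000) / 1000`` clamped at 0
    (air at -1000 HU maps to 0); for HU > breakpoint:
    ``mu = mu_water + (HU - breakpoint) * bone_slope``.  The transform is
    continuous at the breakpoint and monotone non-decreasing.
    """
    if ct.role != Role.HU:
        raise ValueError(f"expected a HU volume, got role {ct.role.value}")
    hu = ct.values
    mu_bp = params.mu_water_cm1 * (params.breakpoint_hu + 1000.0) / 1000.0
    soft = params.mu_water_cm1 * (hu + 1000.0) / 1000.0
    bone = mu_bp + (hu - params.breakpoint_hu) * params.bone_slope_cm1_per_hu
    mu = np.where(hu <= params.breakpoint_hu, soft, bone)
    np.clip(mu, 0.0, None, out=mu)
    return ct.with_values(mu, role=Role.MU_CM1)


def smooth_acm(acm: Volume3, fwhm_mm: float = 13.0) -> Volume3:
    """Isotropic Gaussian smoothing of an attenuation map.

    The default 13 mm FWHM matches the attenuation map to the spatial
    resolution of the reconstructed emission images and absorbs residual
    misregistration.  sigma per axis is ``fwhm / (2 sqrt(2 ln 2))`` in mm,
    converted to voxels via the spacing.  Boundaries use nearest-edge
    replication so body-spanning maps are not darkened at the rim.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm_mm == 0:
        return acm.with_values(acm.values.copy())
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / s for s in acm.spacing_mm]
    out = ndimage.gaussian_filter(acm.values, sigma=sigma_vox, mode="nearest")
    np.clip(out, 0.0, None, out=out)
    return acm.with_values(out)
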