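"""Left-ventricular geometry and AHA 17-segment labelling.

The left ventricle is modelled as a prolate half-ellipsoid shell whose long
axis is aligned with the volume z axis (apex at low z, base at high z), so
axial slices are short-axis slices.  This known orientation replaces the
manual cardiac reorientation performed on clinical images.

Angular convention on a short-axis slice: the anterior wall points in the
-y direction and the septum in the -x direction.  The wall angle theta is
measured from anterior, increasing through the septum (anterior ->
anteroseptal -> inferoseptal -> inferior -> inferolateral -> anterolateral),
matching the standard polar-map display order of the 17-segment model:
segments 1-6 basal, 7-12 mid, 13-16 apical, 17 apex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: fraction of the long axis (from the apex) covered by the apical cap
APEX_FRACTION = 0.25

#: AHA segments per coronary territory (LAD includes the apex; LADwa excludes it)
TERRITORIES = {
    "LAD": (1, 2, 7, 8, 13, 14, 17),
    "LADwa": (1, 2, 7, 8, 13, 14),
    "LCX": (5, 6, 11, 12, 16),
    "RCA": (3, 4, 9, 10, 15),
    "Apex": (17,),
}

SEGMENT_NAMES = {
    1: "basal anterior", 2: "basal anteroseptal", 3: "basal inferoseptal",
    4: "basal inferior", 5: "basal inferolateral", 6: "basal anterolateral",
    7: "mid anterior", 8: "mid anteroseptal", 9: "mid inferoseptal",
    10: "mid inferior", 11: "mid inferolateral", 12: "mid anterolateral",
    13: "apical anterior", 14: "apical septal", 15: "apical inferior",
    16: "apical lateral", 17: "apex",
}


@dataclass(frozen=True)
class LVGeometry:
    """Half-ellipsoid left-ventricle model, long axis along z.

    All coordinates in mm in the volume frame (z, y, x).  The outer surface
    at long-axis coordinate u (0 at the base plane, 1 at the apex tip) has
    transaxial radius ``outer_radius_mm * sqrt(1 - u^2)``; the wall is
    ``wall_mm`` thick and closes into a solid cap at the apex.
    """

    center_yx_mm: tuple[float, float]  # (y, x) of the long axis
    base_z_mm: float
    length_mm: float
    outer_radius_mm: float
    wall_mm: float

    @property
    def apex_z_mm(self) -> float:
        return self.base_z_mm - self.length_mm


def _grids_mm(shape, spacing_mm, origin_mm):
    z = origin_mm[0] + spacing_mm[0] * np.arange(shape[0])
    y = origin_mm[1] + spacing_mm[1] * np.arange(shape[1])
    x = origin_mm[2] + spacing_mm[2] * np.arange(shape[2])
    return np.meshgrid(z, y, x, indexing="ij")


def wall_coordinates(shape, spacing_mm, origin_mm, lv: LVGeometry):
    """Per-voxel LV coordinates: long-axis fraction, radius, wall angle.

    Returns ``(f, r_mm, theta_deg, r_outer_mm)`` arrays over the grid:
    ``f`` runs 0 at the apex tip to 1 at the base plane (NaN outside the
    apex-base z range), ``theta_deg`` in [0, 360) from the anterior wall
    through the septum.
    """
    zg, yg, xg = _grids_mm(shape, spacing_mm, origin_mm)
    cy, cx = lv.center_yx_mm
    u = (lv.base_z_mm - zg) / lv.length_mm  # 0 at base .. 1 at apex
    f = 1.0 - u
    f = np.where((u >= 0.0) & (u <= 1.0), f, np.nan)
    r = np.hypot(yg - cy, xg - cx)
    anterior = -(yg - cy)
    septal = -(xg - cx)
    theta = np.degrees(np.arctan2(septal, anterior)) % 360.0
    with np.errstate(invalid="ignore"):
        r_outer = lv.outer_radius_mm * np.sqrt(np.clip(1.0 - u**2, 0.0, None))
    return f, r, theta, r_outer


def shell_mask(shape, spacing_mm, origin_mm, lv: LVGeometry) -> np.ndarray:
    """Boolean mask of myocardial-wall voxels (shell plus solid apex cap)."""
    f, r, _, r_outer = wall_coordinates(shape, spacing_mm, origin_mm, lv)
    inner = np.maximum(r_outer - lv.wall_mm, 0.0)
    return np.isfinite(f) & (r <= r_outer) & (r >= inner)


def cavity_mask(shape, spacing_mm, origin_mm, lv: LVGeometry) -> np.ndarray:
    """Boolean mask of the blood-pool cavity inside the wall."""
    f, r, _, r_outer = wall_coordinates(shape, spacing_mm, origin_mm, lv)
    inner = np.maximum(r_outer - lv.wall_mm, 0.0)
    return np.isfinite(f) & (r < inner)


def _ring_index(theta_deg: np.ndarray, n_sectors: int) -> np.ndarray:
    """Sector index with the first sector centred on the anterior wall."""
    half = 180.0 / n_sectors
    return np.floor(((theta_deg + half) % 360.0) / (360.0 / n_sectors)).astype(int)


def segment_of(f: np.ndarray, theta_deg: np.ndarray) -> np.ndarray:
    """AHA segment number (1-17) from long-axis fraction and wall angle.

    ``f < APEX_FRACTION`` is the apex (17); the remaining long-axis range is
    split into equal apical / mid / basal bands with 4, 6 and 6 sectors.
    Entries with non-finite ``f`` map to 0 (outside the LV z range).
    """
    f = np.asarray(f, dtype=np.float64)
    theta_deg = np.asarray(theta_deg, dtype=np.float64)
    seg = np.zeros(f.shape, dtype=int)
    ok = np.isfinite(f)
    band = (1.0 - APEX_FRACTION) / 3.0
    apex = ok & (f < APEX_FRACTION)
    apical = ok & (f >= APEX_FRACTION) & (f < APEX_FRACTION + band)
    mid = ok & (f >= APEX_FRACTION + band) & (f < APEX_FRACTION + 2 * band)
    basal = ok & (f >= APEX_FRACTION + 2 * band)
    seg[apex] = 17
    seg[apical] = 13 + _ring_index(theta_deg[apical], 4)
    seg[mid] = 7 + _ring_index(theta_deg[mid], 6)
    seg[basal] = 1 + _ring_index(theta_deg[basal], 6)
    return seg


def segment_labels(shape, spacing_mm, origin_mm, lv: LVGeometry) -> np.ndarray:
    """Voxelwise AHA segment labels on the myocardial shell (0 elsewhere)."""
    f, r, theta, r_outer = wall_coordinates(shape, spacing_mm, origin_mm, lv)
    labels = segment_of(f, theta)
    labels[~shell_mask(shape, spacing_mm, origin_mm, lv)] = 0
    return labels
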