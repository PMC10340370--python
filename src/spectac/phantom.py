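"""Digital thorax phantoms with paired CT and activity volumes.

Generates anatomically plausible (not anatomically detailed) thorax
phantoms: a soft-tissue body ellipse, two lungs, a liver, a spine and a
left-ventricular myocardial shell, each an analytic ellipsoid/cylinder on
the voxel grid.  Every phantom yields a CT volume in Hounsfield units and a
co-aligned 99mTc-sestamibi-like activity volume with known ground truth,
standing in for clinical SPECT/CT pairs.  Perfusion defects are placed by
AHA segment so polar-map scoring can be validated end to end.

Default tissue values span both branches of the bilinear HU->mu transform
(air -1000, lung -700, soft tissue 40, liver 60, spine 400 HU) and the
uptake ratios emulate sestamibi distribution (LV wall 100, liver 60,
lung 5, background 2).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .lvgeom import LVGeometry, segment_labels, shell_mask, cavity_mask, wall_coordinates
from .volume import Role, Volume3

DEFAULT_HU = {"air": -1000.0, "lung": -700.0, "soft": 40.0, "liver": 60.0, "spine": 400.0}
DEFAULT_UPTAKE = {"background": 2.0, "lung": 5.0, "liver": 60.0, "spine": 2.0, "lv_wall": 100.0}


@dataclass(frozen=True)
class DefectSpec:
    """A perfusion defect confined to one AHA segment.

    ``severity`` multiplies the wall activity by ``1 - severity`` inside the
    defect; ``extent`` in (0, 1] shrinks the angular footprint around the
    segment centre (1.0 covers the whole segment).
    """

    segment: int
    severity: float
    extent: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.segment <= 17:
            raise ValueError("segment must be 1..17")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        if not 0.0 < self.extent <= 1.0:
            raise ValueError("extent must lie in (0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of one thorax phantom.

    Lengths in mm, positions as offsets from the grid centre in the
    ``(z, y, x)`` frame (y grows posterior, x grows toward the patient's
    left).  ``z_keep`` is the axial slice range retained after trimming,
    mirroring the 20-30 slice axial coverage of attenuation maps.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (6.9, 6.9, 6.9)
    # body ellipse (transaxial half-axes), extruded along z
    body_half_y_mm: float = 105.0
    body_half_x_mm: float = 150.0
    # lungs: mirrored ellipsoids
    lung_half_zyx_mm: tuple[float, float, float] = (85.0, 55.0, 45.0)
    lung_center_zyx_mm: tuple[float, float, float] = (30.0, -15.0, 62.0)  # |x| mirrored
    # liver ellipsoid (patient right, below the lungs)
    liver_half_zyx_mm: tuple[float, float, float] = (50.0, 60.0, 75.0)
    liver_center_zyx_mm: tuple[float, float, float] = (-75.0, 10.0, -55.0)
    # spine cylinder along z, posterior midline
    spine_radius_mm: float = 16.0
    spine_center_y_mm: float = 72.0
    # left ventricle (anterior left)
    lv_center_zyx_mm: tuple[float, float, float] = (0.0, -30.0, 35.0)
    lv_length_mm: float = 85.0
    lv_outer_radius_mm: float = 40.0
    lv_wall_mm: float = 15.0
    organ_hu: dict = field(default_factory=lambda: dict(DEFAULT_HU))
    organ_activity: dict = field(default_factory=lambda: dict(DEFAULT_UPTAKE))
    ct_noise_hu: float = 20.0
    defect: DefectSpec | None = None
    z_keep: tuple[int, int] = (20, 44)

    def __post_init__(self) -> None:
        nz = self.grid_shape[0]
        z0, z1 = self.z_keep
        if not (0 <= z0 < z1 <= nz):
            raise ValueError(f"z_keep {self.z_keep} outside grid with {nz} slices")
        if not 1 <= z1 - z0 <= nz:
            raise ValueError("z_keep must retain at least one slice")

    @property
    def center_mm(self) -> tuple[float, float, float]:
        return tuple(0.5 * (n - 1) * s for n, s in zip(self.grid_shape, self.spacing_mm))

    def lv_geometry(self) -> LVGeometry:
        cz, cy, cx = self.center_mm
        dz, dy, dx = self.lv_center_zyx_mm
        return LVGeometry(
            center_yx_mm=(cy + dy, cx + dx),
            base_z_mm=cz + dz + 0.5 * self.lv_length_mm,
            length_mm=self.lv_length_mm,
            outer_radius_mm=self.lv_outer_radius_mm,
            wall_mm=self.lv_wall_mm,
        )


def _grids_mm(spec: PhantomSpec):
    z = spec.spacing_mm[0] * np.arange(spec.grid_shape[0])
    y = spec.spacing_mm[1] * np.arange(spec.grid_shape[1])
    x = spec.spacing_mm[2] * np.arange(spec.grid_shape[2])
    return np.meshgrid(z, y, x, indexing="ij")


def organ_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Boolean masks per organ, later organs overwriting earlier ones.

    Returned masks are already disjoint, in drawing order background (body),
    lung, liver, spine, LV cavity, LV wall.
    """
    zg, yg, xg = _grids_mm(spec)
    cz, cy, cx = spec.center_mm

    body = ((yg - cy) / spec.body_half_y_mm) ** 2 + (
        (xg - cx) / spec.body_half_x_mm
    ) ** 2 <= 1.0

    hz, hy, hx = spec.lung_half_zyx_mm
    lz, ly, lx = spec.lung_center_zyx_mm
    lungs = np.zeros(spec.grid_shape, dtype=bool)
    for sx in (+1, -1):
        lungs |= (
            ((zg - cz - lz) / hz) ** 2
            + ((yg - cy - ly) / hy) ** 2
            + ((xg - cx - sx * lx) / hx) ** 2
            <= 1.0
        )

    hz, hy, hx = spec.liver_half_zyx_mm
    vz, vy, vx = spec.liver_center_zyx_mm
    liver = (
        ((zg - cz - vz) / hz) ** 2
        + ((yg - cy - vy) / hy) ** 2
        + ((xg - cx - vx) / hx) ** 2
        <= 1.0
    )

    spine = np.hypot(yg - cy - spec.spine_center_y_mm, xg - cx) <= spec.spine_radius_mm

    lv = spec.lv_geometry()
    geom = (spec.grid_shape, spec.spacing_mm, (0.0, 0.0, 0.0))
    wall = shell_mask(*geom, lv)
    cavity = cavity_mask(*geom, lv)

    if not np.all(body[wall]):
        raise ValueError("LV shell extends outside the body ellipse")
    if not wall.any():
        raise ValueError("LV shell contains no voxels on this grid")

    lungs &= body & ~wall & ~cavity
    liver &= body & ~lungs & ~wall & ~cavity
    spine &= body & ~lungs & ~liver & ~wall & ~cavity
    background = body & ~lungs & ~liver & ~spine & ~wall & ~cavity
    return {
        "background": background,
        "lung": lungs,
        "liver": liver,
        "spine": spine,
        "lv_cavity": cavity,
        "lv_wall": wall,
    }


def defect_mask(spec: PhantomSpec) -> np.ndarray:
    """Voxels of the wall belonging to the configured defect."""
    if spec.defect is None:
        return np.zeros(spec.grid_shape, dtype=bool)
    lv = spec.lv_geometry()
    geom = (spec.grid_shape, spec.spacing_mm, (0.0, 0.0, 0.0))
    labels = segment_labels(*geom, lv)
    mask = labels == spec.defect.segment
    if spec.defect.extent < 1.0 and spec.defect.segment != 17:
        f, _, theta, _ = wall_coordinates(*geom, lv)
        n_sectors = 6 if spec.defect.segment <= 12 else 4
        ring_pos = {1: 0, 2: 1, 3: 2, 4: 3, 5: 4, 6: 5}
        idx = (spec.defect.segment - 1) % 6 if spec.defect.segment <= 12 else spec.defect.segment - 13
        center = idx * (360.0 / n_sectors)
        half = spec.defect.extent * (180.0 / n_sectors)
        dtheta = np.abs((theta - center + 180.0) % 360.0 - 180.0)
        mask &= dtheta <= half
    return mask


def generate_phantom(spec: PhantomSpec, seed: int) -> tuple[Volume3, Volume3]:
    """One CT (HU) / activity pair on the full (untrimmed) grid.

    CT voxels carry the organ HU plus zero-mean Gaussian noise (the paired
    CT scans are of deliberately modest quality); activity voxels carry the
    organ uptake exactly, with the defect region multiplied by
    ``1 - severity``.  Deterministic for a fixed seed.
    """
    masks = organ_masks(spec)
    hu = np.full(spec.grid_shape, spec.organ_hu.get("air", -1000.0), dtype=np.float64)
    act = np.zeros(spec.grid_shape, dtype=np.float64)
    organ_hu = {
        "background": spec.organ_hu["soft"],
        "lung": spec.organ_hu["lung"],
        "liver": spec.organ_hu["liver"],
        "spine": spec.organ_hu["spine"],
        "lv_cavity": spec.organ_hu["soft"],
        "lv_wall": spec.organ_hu["soft"],
    }
    organ_act = {
        "background": spec.organ_activity["background"],
        "lung": spec.organ_activity["lung"],
        "liver": spec.organ_activity["liver"],
        "spine": spec.organ_activity["spine"],
        "lv_cavity": spec.organ_activity["background"],
        "lv_wall": spec.organ_activity["lv_wall"],
    }
    for organ, mask in masks.items():
        hu[mask] = organ_hu[organ]
        act[mask] = organ_act[organ]
    if spec.defect is not None and spec.defect.severity > 0:
        act[defect_mask(spec)] *= 1.0 - spec.defect.severity
    if spec.ct_noise_hu > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, spec.ct_noise_hu, size=spec.grid_shape)
    ct = Volume3(hu, spec.spacing_mm, (0.0, 0.0, 0.0), Role.HU)
    activity = Volume3(act, spec.spacing_mm, (0.0, 0.0, 0.0), Role.ACTIVITY)
    return ct, activity


def jitter_spec(base: PhantomSpec, rng: np.random.Generator, jitter: float = 1.0) -> PhantomSpec:
    """Randomly perturb a base spec within physiological-looking bounds.

    ``jitter`` scales all perturbations; 0 reproduces the base exactly.
    The body scale is drawn from two habitus clusters (smaller and larger
    subjects, emulating female/male strata).
    """
    if jitter == 0.0:
        return base
    female = rng.random() < 0.35
    body_scale = rng.normal(0.88 if female else 1.06, 0.05 * jitter)
    body_scale = 1.0 + jitter * (float(np.clip(body_scale, 0.72, 1.28)) - 1.0)
    j = jitter

    def u(lo, hi):
        return float(rng.uniform(lo, hi))

    lvz, lvy, lvx = base.lv_center_zyx_mm
    defect = base.defect
    z0, z1 = base.z_keep
    n_keep = int(round(np.clip(rng.normal(24, 3 * j), 20, 30)))
    nz = base.grid_shape[0]
    zc = (z0 + z1) // 2 + int(round(u(-2 * j, 2 * j)))
    z0n = int(np.clip(zc - n_keep // 2, 0, nz - n_keep))
    spec = dataclasses.replace(
        base,
        body_half_y_mm=base.body_half_y_mm * body_scale * (1 + j * u(-0.05, 0.05)),
        body_half_x_mm=base.body_half_x_mm * body_scale * (1 + j * u(-0.05, 0.05)),
        lung_half_zyx_mm=tuple(v * body_scale * (1 + j * u(-0.06, 0.06)) for v in base.lung_half_zyx_mm),
        liver_half_zyx_mm=tuple(v * body_scale * (1 + j * u(-0.08, 0.08)) for v in base.liver_half_zyx_mm),
        liver_center_zyx_mm=tuple(c + j * u(-8, 8) for c in base.liver_center_zyx_mm),
        # the heart scales and moves with the chest, plus independent jitter
        lv_center_zyx_mm=(
            lvz + j * u(-7, 7),
            lvy * body_scale + j * u(-6, 6),
            lvx * body_scale + j * u(-6, 6),
        ),
        lv_outer_radius_mm=base.lv_outer_radius_mm * (1 + j * u(-0.08, 0.08)),
        lv_wall_mm=base.lv_wall_mm * (1 + j * u(-0.10, 0.10)),
        organ_activity={
            "background": base.organ_activity["background"] * (1 + j * u(-0.3, 0.3)),
            "lung": base.organ_activity["lung"] * (1 + j * u(-0.4, 0.4)),
            "liver": base.organ_activity["liver"] * (1 + j * u(-0.35, 0.35)),
            "spine": base.organ_activity["spine"] * (1 + j * u(-0.3, 0.3)),
            "lv_wall": base.organ_activity["lv_wall"],
        },
        defect=defect,
        z_keep=(z0n, z0n + n_keep),
    )
    return spec


def phantom_population(
    base: PhantomSpec,
    n: int,
    seed: int,
    jitter: float = 1.0,
    defect_fraction: float = 0.25,
) -> list[tuple[Volume3, Volume3, PhantomSpec]]:
    """A population of jittered phantoms with known per-phantom specs.

    A ``defect_fraction`` of subjects receive a random single-segment
    perfusion defect (severity 0.3-1.0) so that the population contains
    both normal and abnormal studies.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        for _attempt in range(20):
            spec = jitter_spec(base, rng, jitter=jitter)
            if jitter > 0 and base.defect is None and rng.random() < defect_fraction:
                spec = dataclasses.replace(
                    spec,
                    defect=DefectSpec(
                        segment=int(rng.integers(1, 18)),
                        severity=float(rng.uniform(0.3, 1.0)),
                    ),
                )
            try:
                ct, act = generate_phantom(spec, seed=int(rng.integers(0, 2**31 - 1)))
                break
            except ValueError:
                continue  # anatomically impossible draw; redraw
        else:
            raise ValueError("could not draw a valid phantom in 20 attempts")
        out.append((ct, act, spec))
    return out
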