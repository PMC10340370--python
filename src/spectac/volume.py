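"""Voxel volumes for emission/transmission SPECT data.

A :class:`Volume3` wraps a scalar grid indexed ``(z, y, x)`` together with its
voxel spacing and origin in millimetres and a *role* describing the physical
meaning of the voxel values (CT Hounsfield units, linear attenuation
coefficients in cm^-1, activity concentration, or reconstructed values
proportional to photon counts).  Volumes are read and written as NIfTI-1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np


class Role(str, enum.Enum):
    """Physical interpretation of voxel values."""

    HU = "HU"
    MU_CM1 = "MU_CM1"
    ACTIVITY = "ACTIVITY"
    COUNTS_PROP = "COUNTS_PROP"


@dataclass
class Volume3:
    """A 3-D scalar volume with geometry metadata.

    Parameters
    ----------
    values
        Array indexed ``(z, y, x)``.
    spacing_mm
        Voxel spacing per axis ``(z, y, x)`` in mm; default 6.9 mm isotropic.
    origin_mm
        Position of voxel ``(0, 0, 0)`` in mm.
    role
        What the voxel values mean; nonnegativity is enforced for
        attenuation-coefficient and activity volumes.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (6.9, 6.9, 6.9)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: Role = Role.ACTIVITY

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(s) for s in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        self.role = Role(self.role)
        if self.role in (Role.MU_CM1, Role.ACTIVITY) and np.any(self.values < 0):
            raise ValueError(f"role {self.role.value} requires nonnegative values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, role: Role | None = None) -> "Volume3":
        """New volume sharing this volume's geometry."""
        return Volume3(
            values=np.asarray(values, dtype=np.float64),
            spacing_mm=self.spacing_mm,
            origin_mm=self.origin_mm,
            role=self.role if role is None else Role(role),
        )

    def aligned_with(self, other: "Volume3") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def trim_z(self, z_keep: tuple[int, int]) -> "Volume3":
        """Restrict to axial slices ``z_keep[0] <= z < z_keep[1]``.

        Emission volumes are reconstructed on a full 64-slice grid while the
        attenuation information typically covers a narrower axial range
        (20-30 slices); trimming makes the two coincident.
        """
        z0, z1 = int(z_keep[0]), int(z_keep[1])
        nz = self.shape[0]
        if not (0 <= z0 < z1 <= nz):
            raise ValueError(f"z_keep {z_keep} outside grid with {nz} slices")
        new_origin = (
            self.origin_mm[0] + z0 * self.spacing_mm[0],
            self.origin_mm[1],
            self.origin_mm[2],
        )
        return Volume3(self.values[z0:z1].copy(), self.spacing_mm, new_origin, self.role)


_ROLE_KEY = "descrip"  # role round-trips through the NIfTI descrip field


def write_volume(vol: Volume3, path: str) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz), spacing in the header."""
    # NIfTI stores arrays (x, y, z); transpose from our (z, y, x) convention.
    data = np.ascontiguousarray(vol.values.T)
    affine = np.diag(list(vol.spacing_mm[::-1]) + [1.0])
    affine[:3, 3] = vol.origin_mm[::-1]
    img = nib.Nifti1Image(data, affine)
    img.header[_ROLE_KEY] = vol.role.value.encode()
    img.header.set_zooms(vol.spacing_mm[::-1])
    nib.save(img, path)


def read_volume(path: str, role: Role | None = None) -> Volume3:
    """Read a 3-D NIfTI-1 volume.

    The role is taken from the header if it was written by
    :func:`write_volume`, unless overridden by the caller.
    """
    img = nib.load(path)
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    affine = img.affine
    origin = tuple(float(v) for v in affine[:3, 3][::-1])
    if role is None:
        raw = bytes(img.header[_ROLE_KEY].tobytes()).rstrip(b"\x00").decode(errors="replace")
        try:
            role = Role(raw)
        except ValueError:
            role = Role.COUNTS_PROP
    return Volume3(data.T, tuple(float(z) for z in zooms[::-1]), origin, role)
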