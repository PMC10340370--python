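"""Translation-only co-registration with mutual information.

Attenuation maps are aligned to the emission (NAC) volumes with a
three-degree-of-freedom translation maximising the mutual information (MI)
of the joint intensity histogram.  The optimum is found by exhaustive search
over integer-voxel shifts (global and deterministic on these small grids)
followed by a separable quadratic fit to half-voxel precision.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .volume import Volume3


@dataclass(frozen=True)
class RigidShift:
    """A translation (mm, (z, y, x) order) and the MI value it achieves."""

    shift_mm: tuple[float, float, float]
    mi_value: float


def mutual_information(a: Volume3 | np.ndarray, b: Volume3 | np.ndarray, bins: int = 32) -> float:
    """Mutual information of the joint intensity histogram, in nats.

    Symmetric in its arguments and nonnegative; ``MI(x, x)`` equals the
    histogram entropy of ``x``.
    """
    av = a.values if isinstance(a, Volume3) else np.asarray(a)
    bv = b.values if isinstance(b, Volume3) else np.asarray(b)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch {av.shape} vs {bv.shape}")
    hist, _, _ = np.histogram2d(av.ravel(), bv.ravel(), bins=bins)
    p = hist / hist.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    nz = p > 0
    outer = np.outer(pa, pb)
    return float(np.sum(p[nz] * np.log(p[nz] / outer[nz])))


def shift_volume(values: np.ndarray, shift_vox: tuple[int, int, int], fill: float | None = None) -> np.ndarray:
    """Shift by whole voxels, filling exposed regions with the volume minimum."""
    if fill is None:
        fill = float(np.min(values))
    out = np.full_like(values, fill)
    src = []
    dst = []
    for n, d in zip(values.shape, shift_vox):
        d = int(d)
        if abs(d) >= n:
            return out
        if d >= 0:
            dst.append(slice(d, n))
            src.append(slice(0, n - d))
        else:
            dst.append(slice(0, n + d))
            src.append(slice(-d, n))
    out[tuple(dst)] = values[tuple(src)]
    return out


def register_translation(
    moving: Volume3, fixed: Volume3, search_mm: float = 28.0, bins: int = 32
) -> RigidShift:
    """Best translation of ``moving`` onto ``fixed`` by MI grid search.

    Searches all integer-voxel shifts within ``+/- search_mm`` per axis,
    breaking MI ties toward the smallest-norm shift, then refines each axis
    by a quadratic fit through the neighbouring MI values (clamped to half a
    voxel).  Returns the shift to apply to ``moving``.
    """
    if not np.allclose(moving.spacing_mm, fixed.spacing_mm):
        raise ValueError("volumes must share voxel spacing")
    if moving.shape != fixed.shape:
        raise ValueError("volumes must share shape")
    spacing = np.asarray(moving.spacing_mm)
    max_vox = np.floor(search_mm / spacing).astype(int)
    if np.all(max_vox < 1):
        raise ValueError(f"search range {search_mm} mm is below one voxel")
    fill = float(np.min(moving.values))

    mi_cache: dict[tuple[int, int, int], float] = {}

    def mi_at(sv: tuple[int, int, int]) -> float:
        if sv not in mi_cache:
            shifted = shift_volume(moving.values, sv, fill)
            mi_cache[sv] = mutual_information(shifted, fixed.values, bins=bins)
        return mi_cache[sv]

    candidates = sorted(
        itertools.product(*(range(-m, m + 1) for m in max_vox)),
        key=lambda s: (s[0] ** 2 + s[1] ** 2 + s[2] ** 2, s),
    )
    best = max(candidates, key=lambda s: (mi_at(s),))  # ties keep earliest = smallest norm
    # max() keeps the first maximal element, so the smallest-norm candidate wins ties.

    refined = []
    for ax in range(3):
        lo = list(best)
        hi = list(best)
        lo[ax] -= 1
        hi[ax] += 1
        m0 = mi_at(best)
        m_lo = mi_at(tuple(lo))
        m_hi = mi_at(tuple(hi))
        denom = m_lo - 2.0 * m0 + m_hi
        delta = 0.0 if denom >= 0 else 0.5 * (m_lo - m_hi) / denom
        refined.append(best[ax] + float(np.clip(delta, -0.5, 0.5)))
    shift_mm = tuple(float(r * s) for r, s in zip(refined, spacing))
    return RigidShift(shift_mm=shift_mm, mi_value=mi_at(best))


def apply_shift(moving: Volume3, shift: RigidShift) -> Volume3:
    """Apply a registration result (rounded to whole voxels) to a volume."""
    vox = tuple(
        int(round(s / sp)) for s, sp in zip(shift.shift_mm, moving.spacing_mm)
    )
    return moving.with_values(shift_volume(moving.values, vox))
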