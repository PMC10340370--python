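"""Image-quality metrics and agreement statistics.

Implements the metrics used to judge synthetic attenuation maps and the
reconstructions made with them:

* ``mssim`` — mean structural similarity index over sliding Gaussian windows,
  in the standard Wang et al. form ``SSIM = l * c * s`` with a 11x11 window,
  sigma = 1.5 voxels, exponents 1 and C3 = C2/2,
* ``mre`` — mean relative (percentage) error over voxels where the reference
  is informative,
* ``nmae`` — mean absolute error normalised by the reference dynamic range,
* ``mse`` — plain mean squared error,
* ``bland_altman`` — bias and 95% limits of agreement of paired differences.

All metrics accept 2-D images or 3-D volumes (3-D volumes are scored as the
mean over axial slices, matching how stacked tomographic slices are
compared in practice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class SSIMParams:
    """Constants of the structural-similarity index.

    ``data_range`` is the dynamic range L of the image class, fixed per voxel
    role rather than per image so that scores are comparable across subjects:
    1.0 for [0, 1]-normalised emission images and 0.25 cm^-1 for attenuation
    maps (tissue values at 140 keV lie well inside [0, 0.25] cm^-1).
    """

    window_size: int = 11
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 1.0

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2

    @property
    def c3(self) -> float:
        return self.c2 / 2.0


#: SSIM constants for [0,1]-normalised emission images.
EMISSION_SSIM = SSIMParams(data_range=1.0)
#: SSIM constants for attenuation maps in cm^-1.
ACM_SSIM = SSIMParams(data_range=0.25)


def gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    """Normalised 2-D Gaussian window (sums to 1)."""
    half = (size - 1) / 2.0
    ax = np.arange(size) - half
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    w = np.outer(g, g)
    return w / w.sum()


def _filter_valid(img: np.ndarray, size: int, sigma: float) -> np.ndarray:
    """Separable Gaussian correlation restricted to fully-supported windows."""
    half = (size - 1) / 2.0
    ax = np.arange(size) - half
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    g /= g.sum()
    out = ndimage.correlate1d(img, g, axis=0, mode="constant")
    out = ndimage.correlate1d(out, g, axis=1, mode="constant")
    m = size // 2
    return out[m:-m, m:-m] if m else out


def ssim_map(
    y: np.ndarray, yhat: np.ndarray, params: SSIMParams = SSIMParams()
) -> np.ndarray:
    """Per-window SSIM values of a 2-D image pair (valid windows only)."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {yhat.shape}")
    if y.ndim != 2:
        raise ValueError("ssim_map expects 2-D images")
    if min(y.shape) < params.window_size:
        raise ValueError(
            f"image {y.shape} smaller than the {params.window_size}-pixel window"
        )
    size, sigma = params.window_size, params.sigma
    mu_y = _filter_valid(y, size, sigma)
    mu_h = _filter_valid(yhat, size, sigma)
    s_yy = _filter_valid(y * y, size, sigma) - mu_y**2
    s_hh = _filter_valid(yhat * yhat, size, sigma) - mu_h**2
    s_yh = _filter_valid(y * yhat, size, sigma) - mu_y * mu_h
    c1, c2 = params.c1, params.c2
    # l * c * s with C3 = C2/2 collapses to the familiar two-factor form.
    num = (2.0 * mu_y * mu_h + c1) * (2.0 * s_yh + c2)
    den = (mu_y**2 + mu_h**2 + c1) * (s_yy + s_hh + c2)
    return num / den


def mssim(y: np.ndarray, yhat: np.ndarray, params: SSIMParams = SSIMParams()) -> float:
    """Mean SSIM over all sliding windows.

    For 3-D volumes the mean is taken over the per-slice window values (all
    axial slices contribute equally).
    """
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {yhat.shape}")
    if y.ndim == 2:
        return float(np.mean(ssim_map(y, yhat, params)))
    if y.ndim == 3:
        return float(
            np.mean([np.mean(ssim_map(y[z], yhat[z], params)) for z in range(y.shape[0])])
        )
    raise ValueError("mssim expects a 2-D image or 3-D volume")


def mre(y: np.ndarray, yhat: np.ndarray, epsilon: float | None = None) -> float:
    """Mean relative error in percent.

    Averages ``|y - yhat| / (y + eps)`` over voxels where the reference
    exceeds ``eps``; the relative error is unbounded as the reference
    approaches zero, so near-zero reference voxels are excluded.  ``eps``
    defaults to 1e-3 of the reference maximum.
    """
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {yhat.shape}")
    if epsilon is None:
        epsilon = 1e-3 * float(np.max(y))
    mask = y > epsilon
    if not np.any(mask):
        raise ValueError("no reference voxels above epsilon")
    rel = np.abs(y[mask] - yhat[mask]) / (y[mask] + epsilon)
    return float(100.0 * np.mean(rel))


def nmae(y: np.ndarray, yhat: np.ndarray) -> float:
    """Normalised mean absolute error in percent.

    ``100 * sum|y - yhat| / (N * (max(y) - min(y)))`` with the range taken
    from the reference image.
    """
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {yhat.shape}")
    rng = float(np.max(y) - np.min(y))
    if rng <= 0:
        raise ValueError("constant reference image has no dynamic range")
    return float(100.0 * np.mean(np.abs(y - yhat)) / rng)


def mse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean squared error in the squared units of the inputs."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {yhat.shape}")
    return float(np.mean((y - yhat) ** 2))


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement of paired differences."""

    bias: float
    loa_low: float
    loa_high: float
    sd: float
    n_points: int
    percent: bool = True


def bland_altman(
    ref: np.ndarray,
    test: np.ndarray,
    percent: bool = True,
    mask_threshold_fraction: float = 0.10,
) -> BlandAltmanResult:
    """Bland-Altman agreement between paired measurements.

    With ``percent=True`` each difference is expressed as a percentage of the
    reference value, and points where the reference is below
    ``mask_threshold_fraction`` of its maximum are excluded (relative
    differences diverge at zero; low-uptake voxels dominate otherwise).
    With ``percent=False`` raw differences are used and no mask is applied
    (appropriate for e.g. summed-score comparisons).

    Limits of agreement are ``bias +/- 1.96 * sd`` with the sample standard
    deviation (n - 1 denominator).
    """
    ref = np.asarray(ref, dtype=np.float64).ravel()
    test = np.asarray(test, dtype=np.float64).ravel()
    if ref.shape != test.shape:
        raise ValueError("ref and test must have equal lengths")
    if percent:
        keep = ref > mask_threshold_fraction * np.max(ref)
        r, t = ref[keep], test[keep]
        if r.size < 3:
            raise ValueError("fewer than 3 points above the reference mask threshold")
        d = 100.0 * (t - r) / r
    else:
        d = test - ref
        if d.size < 3:
            raise ValueError("fewer than 3 paired points")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd=sd,
        n_points=int(d.size),
        percent=percent,
    )


@dataclass(frozen=True)
class QualityReport:
    """MSSIM / NMAE / MRE / MSE for one volume pair."""

    mssim: float
    nmae_percent: float
    mre_percent: float
    mse: float


def quality_report(
    y: np.ndarray, yhat: np.ndarray, ssim_params: SSIMParams = SSIMParams()
) -> QualityReport:
    """All four quality metrics of an estimate against its reference."""
    return QualityReport(
        mssim=mssim(y, yhat, ssim_params),
        nmae_percent=nmae(y, yhat),
        mre_percent=mre(y, yhat),
        mse=mse(y, yhat),
    )
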