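"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorised code paths: metrics are
computed window-by-window / voxel-by-voxel with plain Python loops, and the
reference MLEM uses an explicit dense system matrix.
"""

from __future__ import annotations

import numpy as np

from spectac.metrics import SSIMParams, gaussian_window


def mssim_bruteforce(y: np.ndarray, yhat: np.ndarray, params: SSIMParams) -> float:
    """Mean SSIM by looping over every fully-supported window."""
    w = gaussian_window(params.window_size, params.sigma)
    k = params.window_size
    c1, c2, c3 = params.c1, params.c2, params.c3
    vals = []
    for i in range(y.shape[0] - k + 1):
        for j in range(y.shape[1] - k + 1):
            a = y[i : i + k, j : j + k]
            b = yhat[i : i + k, j : j + k]
            mu_a = float((w * a).sum())
            mu_b = float((w * b).sum())
            var_a = float((w * (a - mu_a) ** 2).sum())
            var_b = float((w * (b - mu_b) ** 2).sum())
            cov = float((w * (a - mu_a) * (b - mu_b)).sum())
            sa, sb = np.sqrt(var_a), np.sqrt(var_b)
            lum = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
            con = (2 * sa * sb + c2) / (var_a + var_b + c2)
            stru = (cov + c3) / (sa * sb + c3)
            vals.append(lum * con * stru)
    return float(np.mean(vals))


def mre_bruteforce(y: np.ndarray, yhat: np.ndarray, epsilon: float) -> float:
    total, n = 0.0, 0
    for yi, hi in zip(y.ravel(), yhat.ravel()):
        if yi > epsilon:
            total += abs(yi - hi) / (yi + epsilon)
            n += 1
    return 100.0 * total / n


def nmae_bruteforce(y: np.ndarray, yhat: np.ndarray) -> float:
    total = sum(abs(a - b) for a, b in zip(y.ravel(), yhat.ravel()))
    return 100.0 * total / (y.size * (y.max() - y.min()))


def bland_altman_bruteforce(ref, test):
    d = [100.0 * (t - r) / r for r, t in zip(ref, test)]
    bias = sum(d) / len(d)
    sd = np.sqrt(sum((x - bias) ** 2 for x in d) / (len(d) - 1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def dense_system_matrix(projector, shape) -> np.ndarray:
    """Explicit system matrix by projecting unit impulses."""
    nvox = int(np.prod(shape))
    cols = []
    for j in range(nvox):
        e = np.zeros(nvox)
        e[j] = 1.0
        cols.append(projector.forward(e.reshape(shape)).ravel())
    return np.stack(cols, axis=1)


def mlem_dense(A: np.ndarray, y: np.ndarray, x0: np.ndarray, iterations: int, eps=1e-12):
    """Reference MLEM with an explicit matrix, zero-sensitivity voxels frozen."""
    sens = A.sum(axis=0)
    x = x0.copy()
    for _ in range(iterations):
        ratio = y / (A @ x + eps)
        back = A.T @ ratio
        x = np.where(sens > 0, x * back / np.where(sens > 0, sens, 1.0), 0.0)
    return x
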