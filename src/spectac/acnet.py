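"""Attenuation-map generator: a 2-D U-Net trained with an MSSIM+MRE loss.

The generator maps a 64 x 64 x 3 stack of adjacent non-attenuation-corrected
(NAC) emission slices (z-1, z, z+1, normalised to [0, 1]) to the 64 x 64
attenuation-coefficient slice at z (cm^-1, smoothed).  The training loss

    L(Y, Yhat) = alpha * (1 - MSSIM(Y, Yhat)) + (1 - alpha) * MRE(Y, Yhat)

combines structural similarity (subjective appearance, mean-luminance
agreement) with the mean relative error (average fractional deviation of
the predicted attenuation coefficients), weighted by ``alpha`` (default
0.8).  MRE enters the loss as a fraction, not a percentage.

The architecture is a five-level encoder-decoder with symmetric
concatenated skip connections: 3x3 convolutions with batch normalization,
ReLU and dropout, stride-2 convolutions for downsampling, transposed
convolutions for upsampling, and a ReLU output head enforcing mu >= 0.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import nn
from .metrics import ACM_SSIM, SSIMParams, gaussian_window
from .volume import Role, Volume3


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def normalize_volume(nac: Volume3) -> Volume3:
    """Scale an emission volume by its maximum to the range [0, 1].

    Reconstructed intensities vary with dose, scanner sensitivity, delay and
    habitus, so emission images are normalised per volume.  Attenuation maps
    are *never* normalised (they are physical cm^-1 values already within
    [0, 1] cm^-1); passing one raises.
    """
    if nac.role == Role.MU_CM1:
        raise ValueError("attenuation maps are not normalised")
    peak = float(np.max(nac.values))
    if peak <= 0:
        raise ValueError("cannot normalise a volume with no positive values")
    return nac.with_values(nac.values / peak)


@dataclass
class SliceSample:
    """One training pair: (64, 64, 3) NAC input and (64, 64) ACM target."""

    input: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        self.input = np.asarray(self.input, dtype=np.float64)
        self.target = np.asarray(self.target, dtype=np.float64)
        if self.input.ndim != 3 or self.input.shape[2] != 3:
            raise ValueError("input must be (H, W, 3)")
        if self.target.shape != self.input.shape[:2]:
            raise ValueError("target must match the input spatial shape")
        if self.input.min() < -1e-9 or self.input.max() > 1.0 + 1e-9:
            raise ValueError("input slices must be normalised to [0, 1]")
        if self.target.min() < 0:
            raise ValueError("target attenuation values must be nonnegative")


def make_slice_samples(nac: Volume3, acm: Volume3) -> list[SliceSample]:
    """One sample per axial slice, neighbours replicated at the z boundaries."""
    if not nac.aligned_with(acm):
        raise ValueError("NAC and ACM volumes are not aligned")
    nz = nac.shape[0]
    if nz < 1:
        raise ValueError("empty z-extent")
    samples = []
    for z in range(nz):
        zm, zp = max(z - 1, 0), min(z + 1, nz - 1)
        stack = np.stack([nac.values[zm], nac.values[z], nac.values[zp]], axis=-1)
        samples.append(SliceSample(stack, acm.values[z]))
    return samples


@dataclass(frozen=True)
class AugmentPolicy:
    """Random augmentation: in-plane rotation, flips, integer shifts.

    ``flip_axial`` reverses the through-plane channel order (z-1 <-> z+1),
    the 2-D analogue of an axial flip; coronal/sagittal flips mirror the
    slice vertically/horizontally.  The identical transform is applied to
    the input channels and the target.
    """

    rot_z_deg_range: tuple[float, float] = (-5.0, 5.0)
    flip_coronal: bool = True
    flip_sagittal: bool = True
    flip_axial: bool = True
    shift_max_voxels: int = 7
    p_rotate: float = 0.5
    p_flip: float = 0.5
    p_shift: float = 0.5

    def __post_init__(self) -> None:
        if self.shift_max_voxels > 7:
            raise ValueError("shifts are bounded by 7 voxels")


def _shift2d(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.zeros_like(img)
    h, w = img.shape[:2]
    if abs(dy) >= h or abs(dx) >= w:
        return out
    ys = slice(max(dy, 0), min(h, h + dy))
    xs = slice(max(dx, 0), min(w, w + dx))
    yr = slice(max(-dy, 0), min(h, h - dy))
    xr = slice(max(-dx, 0), min(w, w - dx))
    out[ys, xs] = img[yr, xr]
    return out


def augment(
    sample: SliceSample, policy: AugmentPolicy, seed: int | np.random.Generator
) -> SliceSample:
    """Apply one random draw of the policy identically to input and target."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    inp = sample.input.copy()
    tgt = sample.target.copy()
    if rng.random() < policy.p_rotate:
        ang = rng.uniform(*policy.rot_z_deg_range)
        inp = ndimage.rotate(inp, ang, axes=(0, 1), reshape=False, order=1, mode="constant")
        tgt = ndimage.rotate(tgt, ang, axes=(0, 1), reshape=False, order=1, mode="constant")
        np.clip(inp, 0.0, 1.0, out=inp)
        np.clip(tgt, 0.0, None, out=tgt)
    if policy.flip_coronal and rng.random() < policy.p_flip:
        inp = inp[::-1, :, :]
        tgt = tgt[::-1, :]
    if policy.flip_sagittal and rng.random() < policy.p_flip:
        inp = inp[:, ::-1, :]
        tgt = tgt[:, ::-1]
    if policy.flip_axial and rng.random() < policy.p_flip:
        inp = inp[:, :, ::-1]
    if policy.shift_max_voxels > 0 and rng.random() < policy.p_shift:
        dy = int(rng.integers(-policy.shift_max_voxels, policy.shift_max_voxels + 1))
        dx = int(rng.integers(-policy.shift_max_voxels, policy.shift_max_voxels + 1))
        inp = np.stack([_shift2d(inp[..., c], dy, dx) for c in range(3)], axis=-1)
        tgt = _shift2d(tgt, dy, dx)
    return SliceSample(np.ascontiguousarray(inp), np.ascontiguousarray(tgt))


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _ssim_terms(y: np.ndarray, x: np.ndarray, params: SSIMParams):
    """Valid-window SSIM intermediates of target y and prediction x (2-D)."""
    from .metrics import _filter_valid

    size, sig = params.window_size, params.sigma
    F = lambda img: _filter_valid(img, size, sig)
    mu_y = F(y)
    mu_x = F(x)
    u2 = F(x * x)
    u3 = F(x * y)
    s_yy = F(y * y) - mu_y**2
    s_xx = u2 - mu_x**2
    s_xy = u3 - mu_x * mu_y
    a1 = 2.0 * mu_x * mu_y + params.c1
    a2 = 2.0 * s_xy + params.c2
    b1 = mu_x**2 + mu_y**2 + params.c1
    b2 = s_xx + s_yy + params.c2
    return mu_y, mu_x, a1, a2, b1, b2


def _adjoint_filter(d: np.ndarray, out_shape, params: SSIMParams) -> np.ndarray:
    """Adjoint of the valid-window Gaussian filtering (zero-pad + filter)."""
    from .metrics import _filter_valid

    size = params.window_size
    m = size // 2
    padded = np.zeros(out_shape)
    padded[m : m + d.shape[0], m : m + d.shape[1]] = d
    # the filter kernel is symmetric, so the adjoint reuses the same correlation
    half = (size - 1) / 2.0
    ax = np.arange(size) - half
    g = np.exp(-(ax**2) / (2.0 * params.sigma**2))
    g /= g.sum()
    out = ndimage.correlate1d(padded, g, axis=0, mode="constant")
    return ndimage.correlate1d(out, g, axis=1, mode="constant")


def loss(
    target: np.ndarray,
    prediction: np.ndarray,
    alpha: float = 0.8,
    epsilon: float | None = None,
    ssim_params: SSIMParams = ACM_SSIM,
) -> float:
    """The combined training loss for one image pair (MRE as a fraction)."""
    val, _ = loss_and_grad(target, prediction, alpha, epsilon, ssim_params)
    return val


def loss_and_grad(
    target: np.ndarray,
    prediction: np.ndarray,
    alpha: float = 0.8,
    epsilon: float | None = None,
    ssim_params: SSIMParams = ACM_SSIM,
):
    """Loss value and its analytic gradient w.r.t. the prediction.

    The MSSIM gradient follows from differentiating the windowed statistics
    (all of which are Gaussian filterings of the prediction, its square and
    its product with the target); the MRE term contributes
    ``-sign(y - yhat) / (y + eps)`` on the voxels where the target exceeds
    ``eps``.  Verified against finite differences in the test suite.
    """
    y = np.asarray(target, dtype=np.float64)
    x = np.asarray(prediction, dtype=np.float64)
    if y.shape != x.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {x.shape}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if epsilon is None:
        epsilon = 1e-3 * float(np.max(y)) if np.max(y) > 0 else 1e-6

    mu_y, mu_x, a1, a2, b1, b2 = _ssim_terms(y, x, ssim_params)
    p = 1.0 / (b1 * b2)
    s = a1 * a2 * p
    n_win = s.size
    mssim_val = float(np.mean(s))

    ds_du1 = 2.0 * mu_y * p * (a2 - a1) + 2.0 * mu_x * s * (1.0 / b2 - 1.0 / b1)
    ds_du2 = -s / b2
    ds_du3 = 2.0 * a1 * p
    g1 = _adjoint_filter(ds_du1, x.shape, ssim_params)
    g2 = _adjoint_filter(ds_du2, x.shape, ssim_params)
    g3 = _adjoint_filter(ds_du3, x.shape, ssim_params)
    dmssim = (g1 + 2.0 * x * g2 + y * g3) / n_win

    mask = y > epsilon
    if mask.any():
        diff = y - x
        mre_val = float(np.mean(np.abs(diff[mask]) / (y[mask] + epsilon)))
        dmre = np.zeros_like(x)
        dmre[mask] = -np.sign(diff[mask]) / ((y[mask] + epsilon) * mask.sum())
    else:
        mre_val = 0.0
        dmre = np.zeros_like(x)

    value = alpha * (1.0 - mssim_val) + (1.0 - alpha) * mre_val
    grad = -alpha * dmssim + (1.0 - alpha) * dmre
    return float(value), grad


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetConfig:
    """Generator and training hyperparameters.

    Defaults mirror the reference training protocol (Adam, learning rate
    1e-4, loss weight alpha = 0.8, five levels); ``base_channels`` and
    ``batch_size`` are free design parameters chosen small enough for CPU
    training.
    """

    levels: int = 5
    base_channels: int = 32
    dropout_rate: float = 0.1
    alpha: float = 0.8
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    batch_size: int = 16
    max_epochs: int = 800
    patience: int = 20
    seed: int = 0
    restart_every: int | None = None  # warm-restart the optimizer every N epochs
    mre_epsilon: float | None = None
    ssim_data_range: float = 0.25
    dtype: str = "float32"  # parameter/activation precision; float64 for checks
    head_bias: float = 0.05  # output-head bias init, cm^-1 (typical body mean)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")

    @property
    def ssim_params(self) -> SSIMParams:
        return SSIMParams(data_range=self.ssim_data_range)


class UNet(nn.Layer):
    """Five-level encoder-decoder with symmetric skip concatenations."""

    def __init__(self, config: NetConfig, in_channels: int = 3):
        self.config = config
        L = config.levels
        c = config.base_channels
        ch = [c * 2**i for i in range(L)]
        rng = np.random.default_rng(config.seed)
        dr = config.dropout_rate
        dt = np.dtype(config.dtype).type
        self.dtype = dt

        def block(cin, cout):
            return nn.Sequential(
                nn.Conv2d(cin, cout, 3, 1, 1, rng=rng, dtype=dt),
                nn.BatchNorm2d(cout, dtype=dt),
                nn.ReLU(),
                nn.Dropout(dr),
            )

        self.enc = [block(in_channels, ch[0])]
        self.down = []
        for i in range(1, L):
            self.down.append(
                nn.Sequential(
                    nn.Conv2d(ch[i - 1], ch[i], 3, 2, 1, rng=rng, dtype=dt),
                    nn.BatchNorm2d(ch[i], dtype=dt),
                    nn.ReLU(),
                )
            )
            self.enc.append(block(ch[i], ch[i]))
        self.up = []
        self.dec = []
        for i in range(L - 2, -1, -1):
            self.up.append(nn.ConvTranspose2d(ch[i + 1], ch[i], 2, 2, rng=rng, dtype=dt))
            self.dec.append(block(2 * ch[i], ch[i]))
        self.head = nn.Conv2d(ch[0], 1, 1, 1, 0, rng=rng, dtype=dt)
        # start the output at a plausible attenuation level so early training
        # corrects structure rather than global scale
        self.head.b[...] = config.head_bias
        self.out_act = nn.ReLU()

    def params(self):
        mods = self.enc + self.down + self.up + self.dec + [self.head]
        return [p for m in mods for p in m.params()]

    def forward(self, x, training=False, rng=None):
        x = np.ascontiguousarray(x, dtype=self.dtype)
        h, w = x.shape[2], x.shape[3]
        if h % 2 ** (self.config.levels - 1) or w % 2 ** (self.config.levels - 1):
            raise ValueError(
                f"spatial size {h}x{w} not divisible by 2^{self.config.levels - 1}"
            )
        # encoder: skips at levels 0 .. L-2, bottleneck at level L-1
        skips = [self.enc[0].forward(x, training, rng)]
        f = skips[0]
        for i, down in enumerate(self.down):
            f = self.enc[i + 1].forward(down.forward(f, training, rng), training, rng)
            if i < len(self.down) - 1:
                skips.append(f)
        # decoder: up[j] lifts level L-1-j features to level L-2-j
        g = f
        for up, dec, skip in zip(self.up, self.dec, reversed(skips)):
            u = up.forward(g, training, rng)
            g = dec.forward(np.concatenate([u, skip], axis=1), training, rng)
        out = self.head.forward(g, training, rng)
        return self.out_act.forward(out, training, rng)

    def backward(self, dy):
        d = self.head.backward(self.out_act.backward(dy))
        L = self.config.levels
        dskips: list = [None] * (L - 1)
        for j in range(len(self.dec) - 1, -1, -1):
            level = L - 2 - j  # skip level consumed by decoder stage j
            dcat = self.dec[j].backward(d)
            half = dcat.shape[1] // 2  # up output and skip have equal widths
            dskips[level] = dcat[:, half:]
            d = self.up[j].backward(dcat[:, :half])
        for i in range(len(self.down) - 1, -1, -1):
            if i + 1 <= L - 2:
                d = d + dskips[i + 1]
            d = self.down[i].backward(self.enc[i + 1].backward(d))
        return self.enc[0].backward(d + dskips[0])

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode forward pass (running BN stats, no dropout)."""
        return self.forward(x, training=False)


def build_unet(config: NetConfig, in_channels: int = 3) -> UNet:
    """Construct the generator with seeded weight initialisation."""
    return UNet(config, in_channels=in_channels)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _batch_arrays(samples: list[SliceSample]):
    x = np.stack([s.input.transpose(2, 0, 1) for s in samples])  # (N, 3, H, W)
    y = np.stack([s.target for s in samples])  # (N, H, W)
    return x, y


def batch_loss_and_grad(
    targets: np.ndarray,
    predictions: np.ndarray,
    alpha: float = 0.8,
    epsilon: float | None = None,
    ssim_params: SSIMParams = ACM_SSIM,
):
    """Mean loss over a batch of image pairs and its gradient.

    Vectorised over the leading batch axis: the Gaussian filterings of the
    SSIM statistics run on the full ``(N, H, W)`` stacks.  Equivalent to
    averaging :func:`loss_and_grad` over the batch.
    """
    y = np.asarray(targets, dtype=np.float64)
    x = np.asarray(predictions, dtype=np.float64)
    if y.shape != x.shape or y.ndim != 3:
        raise ValueError("expected matching (N, H, W) stacks")
    n = y.shape[0]
    size, sig = ssim_params.window_size, ssim_params.sigma
    # filtering is separable and per-image; run it on contiguous stacks
    half = (size - 1) / 2.0
    ax = np.arange(size) - half
    g = np.exp(-(ax**2) / (2.0 * sig**2))
    g /= g.sum()

    def stack_filter(img):
        out = ndimage.correlate1d(img, g, axis=1, mode="constant")
        out = ndimage.correlate1d(out, g, axis=2, mode="constant")
        m = size // 2
        return out[:, m:-m, m:-m] if m else out

    mu_y = stack_filter(y)
    mu_x = stack_filter(x)
    u2 = stack_filter(x * x)
    u3 = stack_filter(x * y)
    s_yy = stack_filter(y * y) - mu_y**2
    s_xx = u2 - mu_x**2
    s_xy = u3 - mu_x * mu_y
    c1, c2 = ssim_params.c1, ssim_params.c2
    a1 = 2.0 * mu_x * mu_y + c1
    a2 = 2.0 * s_xy + c2
    b1 = mu_x**2 + mu_y**2 + c1
    b2 = s_xx + s_yy + c2
    p = 1.0 / (b1 * b2)
    s = a1 * a2 * p
    n_win = s.shape[1] * s.shape[2]
    mssim_per = s.mean(axis=(1, 2))

    ds_du1 = 2.0 * mu_y * p * (a2 - a1) + 2.0 * mu_x * s * (1.0 / b2 - 1.0 / b1)
    ds_du2 = -s / b2
    ds_du3 = 2.0 * a1 * p
    m = size // 2

    def stack_adjoint(d):
        padded = np.zeros(y.shape)
        padded[:, m : m + d.shape[1], m : m + d.shape[2]] = d
        out = ndimage.correlate1d(padded, g, axis=1, mode="constant")
        return ndimage.correlate1d(out, g, axis=2, mode="constant")

    dmssim = (
        stack_adjoint(ds_du1) + 2.0 * x * stack_adjoint(ds_du2) + y * stack_adjoint(ds_du3)
    ) / n_win

    if epsilon is None:
        peaks = y.max(axis=(1, 2), keepdims=True)
        eps = 1e-3 * np.where(peaks > 0, peaks, 1e-3)
    else:
        eps = np.full((n, 1, 1), float(epsilon))
    mask = y > eps
    counts = mask.sum(axis=(1, 2))
    diff = y - x
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(mask, np.abs(diff) / (y + eps), 0.0)
    mre_per = np.where(counts > 0, rel.sum(axis=(1, 2)) / np.maximum(counts, 1), 0.0)
    dmre = np.where(
        mask, -np.sign(diff) / ((y + eps) * np.maximum(counts, 1)[:, None, None]), 0.0
    )

    per_sample = alpha * (1.0 - mssim_per) + (1.0 - alpha) * mre_per
    grad = (-alpha * dmssim + (1.0 - alpha) * dmre) / n
    return float(per_sample.mean()), grad


def _batch_loss_and_grad(model, x, y, config: NetConfig, training, rng):
    pred = model.forward(x, training=training, rng=rng)[:, 0].astype(np.float64)
    value, dpred = batch_loss_and_grad(
        y, pred, config.alpha, config.mre_epsilon, config.ssim_params
    )
    return value, dpred[:, None, :, :].astype(model.dtype)


def evaluate_loss(model, samples: list[SliceSample], config: NetConfig) -> float:
    """Mean loss over samples in evaluation mode."""
    x, y = _batch_arrays(samples)
    total = 0.0
    bs = max(config.batch_size, 1)
    for i in range(0, len(samples), bs):
        pred = model.forward(x[i : i + bs], training=False)[:, 0].astype(np.float64)
        value, _ = batch_loss_and_grad(
            y[i : i + bs], pred, config.alpha, config.mre_epsilon, config.ssim_params
        )
        total += value * pred.shape[0]
    return total / len(samples)


def train(
    model: UNet,
    train_samples: list[SliceSample],
    val_samples: list[SliceSample],
    config: NetConfig,
    augment_policy: AugmentPolicy | None = None,
) -> tuple[UNet, dict]:
    """Minimise the combined loss with early stopping on validation loss.

    Records per-epoch train/validation losses, stops once the validation
    loss has not improved for ``patience`` epochs and restores the best
    validation-loss weights.  With ``restart_every`` set, the optimizer
    moments are re-initialised every that many epochs (warm restarts) —
    the momentary larger steps help escape the plateaus the structural-
    similarity term produces.  Fully deterministic for a fixed config seed.
    """
    if not train_samples or not val_samples:
        raise ValueError("training and validation sets must be nonempty")
    rng = np.random.default_rng(config.seed + 1)

    def make_opt():
        if config.optimizer.lower() == "adam":
            return nn.Adam(model, lr=config.learning_rate)
        if config.optimizer.lower() == "sgd":
            return nn.SGD(model, lr=config.learning_rate)
        raise ValueError(f"unknown optimizer {config.optimizer!r}")

    opt = make_opt()
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = nn.get_state(model)
    since_best = 0
    n = len(train_samples)
    for epoch in range(config.max_epochs):
        if config.restart_every and epoch > 0 and epoch % config.restart_every == 0:
            opt = make_opt()
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            batch_idx = order[start : start + config.batch_size]
            batch = [train_samples[i] for i in batch_idx]
            if augment_policy is not None:
                batch = [augment(s, augment_policy, rng) for s in batch]
            x, y = _batch_arrays(batch)
            nn.zero_grads(model)
            value, dpred = _batch_loss_and_grad(model, x, y, config, True, rng)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {value}"
                )
            model.backward(dpred)
            opt.step()
            epoch_loss += value
            n_batches += 1
        val = evaluate_loss(model, val_samples, config)
        history["train_loss"].append(epoch_loss / n_batches)
        history["val_loss"].append(val)
        if val < best_val - 1e-9:
            best_val = val
            best_state = nn.get_state(model)
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    nn.set_state(model, best_state)
    return model, history


@dataclass(frozen=True)
class MuCalibration:
    """Monotone intensity recalibration of predicted attenuation values.

    The structural-similarity term of the training loss is only weakly
    sensitive to a global attenuation scale (its luminance factor saturates
    near 1 for small relative offsets), so a trained generator can settle
    with a few-percent systematic shift in tissue-level mu that line
    integrals then amplify.  The curve maps predicted mu to the mean target
    mu observed in prediction-quantile bins on held-back validation data;
    enforced monotone and applied by linear interpolation.
    """

    x: np.ndarray
    y: np.ndarray

    def __call__(self, values: np.ndarray) -> np.ndarray:
        return np.interp(values, self.x, self.y, left=0.0, right=self.y[-1])


def fit_mu_calibration(
    predictions: np.ndarray, targets: np.ndarray, n_bins: int = 40, min_count: int = 50
) -> MuCalibration:
    """Fit a monotone prediction->target curve on validation voxels."""
    p = np.asarray(predictions, dtype=np.float64).ravel()
    t = np.asarray(targets, dtype=np.float64).ravel()
    if p.shape != t.shape:
        raise ValueError("predictions and targets must have equal sizes")
    pos = p[p > 1e-4]
    if pos.size < 10 * min_count:
        raise ValueError("too few positive voxels to fit a calibration curve")
    edges = np.unique(np.concatenate([[0.0], np.quantile(pos, np.linspace(0, 1, n_bins + 1))]))
    idx = np.digitize(p, edges) - 1
    xs, ys = [0.0], [0.0]
    for i in range(len(edges) - 1):
        m = idx == i
        if m.sum() >= min_count:
            xs.append(float(p[m].mean()))
            ys.append(float(t[m].mean()))
    x = np.asarray(xs)
    y = np.maximum.accumulate(np.asarray(ys))
    return MuCalibration(x=x, y=np.clip(y, 0.0, None))


def calibrate_predictions(
    model: "UNet", val_samples: list[SliceSample]
) -> MuCalibration:
    """Fit :class:`MuCalibration` from a model's validation predictions."""
    x, y = _batch_arrays(val_samples)
    preds = []
    for i in range(0, len(val_samples), 16):
        preds.append(model.predict(x[i : i + 16])[:, 0])
    return fit_mu_calibration(np.concatenate(preds), y)


def predict_acm(
    model: "UNet", nac: Volume3, calibration: MuCalibration | None = None
) -> Volume3:
    """Per-slice prediction of an attenuation map from a normalised NAC volume.

    The NAC volume must be [0, 1]-normalised; slices are converted to
    3-channel samples (neighbour replication at the z boundaries) and the
    predictions reassembled into a volume with the input geometry.
    """
    if float(np.max(nac.values)) > 1.0 + 1e-9:
        raise ValueError("NAC volume must be normalised before prediction")
    nz = nac.shape[0]
    stacks = []
    for z in range(nz):
        zm, zp = max(z - 1, 0), min(z + 1, nz - 1)
        stacks.append(np.stack([nac.values[zm], nac.values[z], nac.values[zp]]))
    x = np.stack(stacks)  # (Z, 3, H, W)
    preds = []
    for i in range(0, nz, 16):
        preds.append(model.predict(x[i : i + 16])[:, 0])
    out = np.concatenate(preds, axis=0).astype(np.float64)
    if calibration is not None:
        out = calibration(out)
    return Volume3(np.clip(out, 0.0, None), nac.spacing_mm, nac.origin_mm, Role.MU_CM1)


def hyperparameter_search(
    train_samples: list[SliceSample],
    val_samples: list[SliceSample],
    base: NetConfig,
    space: dict[str, list],
    n_trials: int = 4,
    seed: int = 0,
) -> tuple[NetConfig, list[tuple[NetConfig, float]]]:
    """Small random search over a config space, scored by validation loss.

    A deliberately light-weight stand-in for large random hyperparameter
    sweeps: draws ``n_trials`` random combinations from ``space`` (lists of
    candidate values per NetConfig field), trains each and returns the best
    config plus all (config, val_loss) results.
    """
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_trials):
        draw = {k: v[rng.integers(len(v))] for k, v in space.items()}
        cfg = replace(base, **draw)
        model = build_unet(cfg)
        model, hist = train(model, train_samples, val_samples, cfg)
        results.append((cfg, min(hist["val_loss"])))
    best = min(results, key=lambda t: t[1])[0]
    return best, results
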