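"""Structure-preserving denoising for micrographs.

Two stages, composable in five orderings (A1-A5):

* Zero-shot Noise2Noise: the image is split into two half-resolution
  siblings by fixed 2x2 diagonal-averaging kernels; a tiny per-image
  convolutional network is fitted to predict the noise with a residual +
  consistency objective, then discarded. No training data, no pretrained
  weights.
* A classical chain: Gaussian blur -> non-local means -> Wiener, then
  CLAHE for local contrast and a guided filter that fuses the denoised
  image with the CLAHE output to sharpen particle boundaries.

Mode A5 (unsupervised followed by traditional) is the default ordering;
A1 = no denoising, A2 = chain only, A3 = ZS-N2N only, A4 = chain then
ZS-N2N. All modes return intensities min-max scaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage.exposure import equalize_adapthist
from skimage.restoration import denoise_nl_means

from . import nn
from .io_star import Micrograph
from .nn import tensor as T

MODES = ("A1", "A2", "A3", "A4", "A5")


@dataclass
class DenoiseConfig:
    """Denoising parameters.

    ``nlm_h`` is a multiplier on the estimated noise sigma (the non-local
    means filter strength is ``nlm_h * sigma_est``). ``clahe_clip`` uses
    the familiar OpenCV-style scale (2.0 ~ clip fraction 0.02).
    """

    mode: str = "A5"
    zsn2n_steps: int = 1000
    zsn2n_lr: float = 5e-3
    zsn2n_width: int = 48
    seed: int = 0
    gaussian_sigma: float = 1.0
    nlm_h: float = 0.8
    wiener_window: int = 5
    clahe_clip: float = 2.0
    clahe_tile: int = 8
    guided_radius: int = 8
    guided_eps: float = 1e-2

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown denoise mode {self.mode!r}; expected {MODES}")
        if self.wiener_window % 2 == 0 or self.wiener_window < 1:
            raise ValueError("wiener_window must be odd and positive")


def minmax(img):
    """Scale to [0, 1]; a constant image maps to zeros."""
    img = np.asarray(img, dtype=np.float32)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def estimate_noise_sigma(img) -> float:
    """Noise sigma via median absolute deviation of the Laplacian.

    For iid Gaussian noise the 3x3 Laplacian response has variance
    20*sigma^2, so sigma = MAD(lap) / (0.6745 * sqrt(20)).
    """
    lap = ndimage.laplace(np.asarray(img, dtype=np.float64))
    mad = np.median(np.abs(lap - np.median(lap)))
    return float(mad / (0.6745 * np.sqrt(20.0)))


def pair_downsample(img):
    """Split into two half-size siblings with fixed diagonal kernels.

    Each 2x2 tile [[a, b], [c, d]] contributes (a+d)/2 to the first
    sibling and (b+c)/2 to the second. Odd trailing rows/columns are
    cropped.
    """
    img = np.asarray(img)
    h, w = img.shape[-2:]
    img = img[..., : h - h % 2, : w - w % 2]
    a = img[..., 0::2, 0::2]
    b = img[..., 0::2, 1::2]
    c = img[..., 1::2, 0::2]
    d = img[..., 1::2, 1::2]
    return (a + d) / 2.0, (b + c) / 2.0


class _NoiseNet(nn.Module):
    """Two 3x3 conv layers (1 -> width -> 1) predicting the noise map."""

    def __init__(self, width, rng):
        self.c1 = nn.Conv2d(1, width, 3, rng)
        self.c2 = nn.Conv2d(width, 1, 3, rng)

    def forward(self, x):
        return self.c2(T.relu(self.c1(x)))


def zsn2n_denoise(m: Micrograph, cfg: DenoiseConfig) -> Micrograph:
    """Per-image zero-shot Noise2Noise.

    The image is standardized, a fresh network is fitted with the
    residual + consistency loss, the predicted noise is subtracted and the
    original scale restored. Deterministic given ``cfg.seed``; no state
    persists between images.
    """
    img = np.asarray(m.pixels, dtype=np.float32)
    if not np.all(np.isfinite(img)):
        raise ValueError("zsn2n_denoise: input contains non-finite values")
    if img.shape[0] < 8 or img.shape[1] < 8:
        raise ValueError(f"zsn2n_denoise: image {img.shape} smaller than 8x8")

    mean, std = float(img.mean()), float(img.std())
    std = std if std > 0 else 1.0
    x = (img - mean) / std

    rng = np.random.default_rng(cfg.seed)
    net = _NoiseNet(cfg.zsn2n_width, rng)
    opt = nn.Adam(net.parameters(), lr=cfg.zsn2n_lr)

    d1_np, d2_np = pair_downsample(x)
    xt = nn.Tensor(x[None, None])
    # the two siblings share one batched forward pass
    d = nn.Tensor(np.stack([d1_np, d2_np])[:, None])
    d_swapped = nn.Tensor(np.stack([d2_np, d1_np])[:, None])

    def mse(a, b):
        diff = a - b
        return T.reduce_mean(diff * diff)

    g = d_swapped  # consistency target; refreshed periodically below
    for step in range(cfg.zsn2n_steps):
        opt.zero_grad()
        if step % 10 == 0:
            # stop-gradient target: downsampled current full-image estimate
            fx = net(xt).data[0, 0]
            g1_np, g2_np = pair_downsample(x - fx)
            g = nn.Tensor(np.stack([g1_np, g2_np])[:, None])
        fd = net(d)
        loss_res = mse(d - fd, d_swapped)
        loss_cons = mse(d - fd, g)
        (loss_res + loss_cons).backward()
        opt.step()

    out = x - net(nn.Tensor(x[None, None])).data[0, 0]
    return m.with_pixels((out * std + mean).astype(np.float32))


def guided_filter(guide, src, radius, eps):
    """Edge-preserving smoothing of ``src`` steered by ``guide``.

    Local linear model q = a*I + b per window; in the large-eps limit the
    output approaches the box mean of ``src``.
    """
    guide = np.asarray(guide, dtype=np.float64)
    src = np.asarray(src, dtype=np.float64)
    size = 2 * int(radius) + 1

    def box(u):
        return ndimage.uniform_filter(u, size=size, mode="reflect")

    mean_i, mean_p = box(guide), box(src)
    corr_i, corr_ip = box(guide * guide), box(guide * src)
    var_i = corr_i - mean_i * mean_i
    cov_ip = corr_ip - mean_i * mean_p
    a = cov_ip / (var_i + eps)
    b = mean_p - a * mean_i
    return box(a) * guide + box(b)


def classical_chain(m: Micrograph, cfg: DenoiseConfig) -> Micrograph:
    """Gaussian -> non-local means -> Wiener -> CLAHE -> guided fusion."""
    img = np.asarray(m.pixels, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("classical_chain: input contains non-finite values")
    h, w = img.shape
    if cfg.wiener_window > min(h, w):
        raise ValueError("wiener_window larger than the image")
    if min(h, w) // cfg.clahe_tile < 1:
        raise ValueError("clahe_tile larger than the image")

    x = minmax(img).astype(np.float64)
    x = ndimage.gaussian_filter(x, sigma=cfg.gaussian_sigma)
    sigma = estimate_noise_sigma(x)
    if sigma > 0:
        x = denoise_nl_means(
            x, h=cfg.nlm_h * sigma, sigma=sigma, patch_size=5,
            patch_distance=6, fast_mode=True,
        )
    x = signal.wiener(x, mysize=cfg.wiener_window)
    x = np.nan_to_num(x, nan=0.0)

    denoised = minmax(x).astype(np.float64)
    kernel = (max(1, h // cfg.clahe_tile), max(1, w // cfg.clahe_tile))
    if denoised.max() > denoised.min():
        clahe = equalize_adapthist(
            denoised, kernel_size=kernel, clip_limit=cfg.clahe_clip / 100.0
        )
    else:
        clahe = denoised
    fused = guided_filter(clahe, denoised, cfg.guided_radius, cfg.guided_eps)
    return m.with_pixels(minmax(fused))


def preprocess(m: Micrograph, cfg: DenoiseConfig) -> Micrograph:
    """Dispatch on ``cfg.mode``; every mode returns intensities in [0, 1]."""
    if cfg.mode == "A1":
        return m.with_pixels(minmax(m.pixels))
    if cfg.mode == "A2":
        return classical_chain(m, cfg)
    if cfg.mode == "A3":
        return m.with_pixels(minmax(zsn2n_denoise(m, cfg).pixels))
    if cfg.mode == "A4":
        return m.with_pixels(minmax(zsn2n_denoise(classical_chain(m, cfg), cfg).pixels))
    if cfg.mode == "A5":
        return classical_chain(zsn2n_denoise(m, cfg), cfg)
    raise ValueError(f"unknown denoise mode {cfg.mode!r}")


def psnr(reference, img, affine=True) -> float:
    """PSNR of ``img`` against a clean reference.

    With ``affine`` (default) the image is first least-squares mapped
    through a*img + b, so the measure is invariant to the intensity
    rescaling the denoising modes apply.
    """
    ref = np.asarray(reference, dtype=np.float64).ravel()
    x = np.asarray(img, dtype=np.float64).ravel()
    if affine:
        A = np.stack([x, np.ones_like(x)], axis=1)
        coef, *_ = np.linalg.lstsq(A, ref, rcond=None)
        x = A @ coef
    mse = float(np.mean((x - ref) ** 2))
    rng_ = float(ref.max() - ref.min())
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(rng_**2 / mse))
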