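"""Image quality metrics: PSNR and SSIM.

PSNR is the standard ``10 log10(MAX^2 / MSE)`` with configurable dynamic
range (default 1.0 for [0, 1]-normalized images; 255 for 8-bit scale).

SSIM multiplies luminance, contrast, and structure terms (all exponents
1).  The windowed default follows the community-standard protocol:
11x11 Gaussian window with sigma = 1.5, C1 = (0.01 L)^2, C2 = (0.03 L)^2,
C3 = C2/2, mean-pooled over the image with the half-window border
cropped.  A "global" single-window mode evaluates the raw three-term
formula once over the whole image, which is convenient for testing its
algebra (e.g. the structure term of an image against its negation tends
to -1 as the stabilizers vanish).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["SsimConsts", "psnr", "ssim", "mse"]


@dataclass
class SsimConsts:
    max_val: float = 1.0
    k1: float = 0.01
    k2: float = 0.03
    sigma: float = 1.5
    window: str = "gaussian"  # "gaussian" | "global"

    @property
    def C1(self) -> float:
        return (self.k1 * self.max_val) ** 2

    @property
    def C2(self) -> float:
        return (self.k2 * self.max_val) ** 2

    @property
    def C3(self) -> float:
        return self.C2 / 2.0


def _check_shapes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def mse(x: np.ndarray, y: np.ndarray) -> float:
    x, y = _check_shapes(x, y)
    return float(np.mean((x - y) ** 2))


def psnr(x: np.ndarray, y: np.ndarray, max_val: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    if max_val <= 0:
        raise ValueError("max_val must be > 0")
    err = mse(x, y)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_val**2 / err))


def _ssim_terms(mu_x, mu_y, var_x, var_y, cov, consts: SsimConsts):
    c1, c2, c3 = consts.C1, consts.C2, consts.C3
    sd_x = np.sqrt(np.maximum(var_x, 0.0))
    sd_y = np.sqrt(np.maximum(var_y, 0.0))
    lum = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
    con = (2 * sd_x * sd_y + c2) / (var_x + var_y + c2)
    struct = (cov + c3) / (sd_x * sd_y + c3)
    return lum * con * struct


def ssim(x: np.ndarray, y: np.ndarray, consts: SsimConsts | None = None) -> float:
    """Structural similarity: luminance x contrast x structure, in [-1, 1]."""
    consts = consts or SsimConsts()
    x, y = _check_shapes(x, y)

    if consts.window == "global":
        mu_x, mu_y = x.mean(), y.mean()
        var_x, var_y = x.var(), y.var()
        cov = float(np.mean((x - mu_x) * (y - mu_y)))
        return float(_ssim_terms(mu_x, mu_y, var_x, var_y, cov, consts))

    # 11x11 Gaussian window: radius 5 at sigma 1.5
    truncate = 5.0 / consts.sigma

    def smooth(a):
        return gaussian_filter(a, consts.sigma, truncate=truncate, mode="nearest")

    mu_x = smooth(x)
    mu_y = smooth(y)
    var_x = smooth(x * x) - mu_x**2
    var_y = smooth(y * y) - mu_y**2
    cov = smooth(x * y) - mu_x * mu_y
    smap = _ssim_terms(mu_x, mu_y, var_x, var_y, cov, consts)
    pad = 5
    if min(smap.shape) > 2 * pad:
        smap = smap[pad:-pad, pad:-pad]
    return float(smap.mean())
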