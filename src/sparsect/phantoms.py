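"""Synthetic phantom generation and image I/O.

Provides the classic Shepp-Logan head phantom and seeded random-ellipse
phantoms that stand in for real chest-CT slices, plus the paired
(sparse sinogram, full sinogram, reference image) dataset builder used
for training and evaluation.  All phantom support lies inside the
inscribed circle of the image so that parallel-beam projections with
detector span equal to the image side lose no mass.

Images are square, even-sided, float arrays with values in [0, 1].
Ellipse edges are anti-aliased by 4x4 area-fraction supersampling:
hard edges would create gridding artifacts unrelated to the angular
undersampling streaks the reconstruction networks are trained on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .projection import Geometry, Sinogram, radon_forward, subsample_views

__all__ = [
    "PhantomSpec",
    "shepp_logan",
    "random_ellipses",
    "make_paired_dataset",
    "validate_image",
    "save_image",
    "load_image",
    "load_dicom",
]

_SUPERSAMPLE = 4

# Modified Shepp-Logan ellipses (value, a, b, x0, y0, phi_deg) in the
# [-1, 1]^2 unit square; the "modified" contrast variant whose summed
# intensities already lie in [0, 1].
_SHEPP_LOGAN = [
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
]


@dataclass
class PhantomSpec:
    """Parameters of a seeded random-ellipse phantom.

    ``n_ellipses`` may be a single count or an inclusive (lo, hi) range
    drawn per phantom.  ``seed`` fully determines the output.
    """

    size: int = 64
    n_ellipses: int | tuple[int, int] = (5, 12)
    intensity_range: tuple[float, float] = (0.2, 1.0)
    seed: int = 0
    wavelet_levels: int = 3

    def __post_init__(self) -> None:
        if self.size < 16 or self.size % 2:
            raise ValueError("size must be even and >= 16")
        if self.size % (2**self.wavelet_levels):
            raise ValueError(
                f"size {self.size} not divisible by 2^{self.wavelet_levels}"
            )
        lo, hi = self._count_range()
        if lo < 1 or hi < lo:
            raise ValueError("n_ellipses must be >= 1")
        ilo, ihi = self.intensity_range
        if not (0.0 <= ilo <= ihi <= 1.0):
            raise ValueError("intensity_range must satisfy 0 <= lo <= hi <= 1")

    def _count_range(self) -> tuple[int, int]:
        if isinstance(self.n_ellipses, int):
            return self.n_ellipses, self.n_ellipses
        lo, hi = self.n_ellipses
        return int(lo), int(hi)


def validate_image(pixels: np.ndarray) -> np.ndarray:
    """Check the Image invariants: square, even, finite, values in [0, 1]."""
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError(f"image must be square 2D, got shape {pixels.shape}")
    if pixels.shape[0] % 2:
        raise ValueError("image side must be even")
    if not np.all(np.isfinite(pixels)):
        raise ValueError("image contains non-finite values")
    if pixels.min() < 0.0 or pixels.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    return pixels


def _rasterize(
    size: int, ellipses: list[tuple[float, float, float, float, float, float]]
) -> np.ndarray:
    """Sum ellipses on a [-1,1]^2 grid with supersampled (anti-aliased) edges.

    Row index increases downward; y increases upward, matching the usual
    head-phantom orientation.
    """
    s = _SUPERSAMPLE
    n = size * s
    # supersampled pixel centers
    coords = (np.arange(n) + 0.5) / n * 2.0 - 1.0
    xg = coords[None, :]
    yg = -coords[:, None]
    img = np.zeros((n, n))
    for value, a, b, x0, y0, phi in ellipses:
        phi_r = np.deg2rad(phi)
        c, sn = np.cos(phi_r), np.sin(phi_r)
        xr = (xg - x0) * c + (yg - y0) * sn
        yr = -(xg - x0) * sn + (yg - y0) * c
        img += value * ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
    # area-fraction average back to the target grid
    img = img.reshape(size, s, size, s).mean(axis=(1, 3))
    return img


def shepp_logan(size: int) -> np.ndarray:
    """Standard 10-ellipse Shepp-Logan head phantom, values in [0, 1]."""
    if size < 16 or size % 2:
        raise ValueError("size must be even and >= 16")
    img = _rasterize(size, _SHEPP_LOGAN)
    return np.clip(img, 0.0, 1.0)


def random_ellipses(spec: PhantomSpec) -> np.ndarray:
    """Seeded random-ellipse phantom: overlapping soft-edged ellipses.

    Intensities add (mimicking overlapping tissue densities) and the sum
    is clipped to [0, 1].  Identical spec -> bitwise identical output.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec._count_range()
    n = int(rng.integers(lo, hi + 1))
    ilo, ihi = spec.intensity_range
    ellipses = []
    for _ in range(n):
        # keep each ellipse inside 0.9 x the inscribed circle
        a = rng.uniform(0.05, 0.45)
        b = rng.uniform(0.05, 0.45)
        r_max = 0.9 - max(a, b)
        r = rng.uniform(0.0, max(r_max, 0.0))
        theta = rng.uniform(0.0, 2.0 * np.pi)
        x0, y0 = r * np.cos(theta), r * np.sin(theta)
        phi = rng.uniform(0.0, 180.0)
        value = rng.uniform(ilo, ihi)
        ellipses.append((value, a, b, x0, y0, phi))
    img = _rasterize(spec.size, ellipses)
    return np.clip(img, 0.0, 1.0)


def make_paired_dataset(
    n_images: int,
    spec: PhantomSpec,
    geometry: Geometry,
    factor: int,
    seed: int | None = None,
) -> list[tuple[Sinogram, Sinogram, np.ndarray]]:
    """Build index-aligned (sparse sinogram, full sinogram, image) triplets.

    The full sinogram is the forward projection of each phantom on
    ``geometry``; the sparse sinogram keeps every ``factor``-th view.
    ``seed`` (default: spec.seed) shifts the per-phantom seeds.
    """
    if n_images < 0:
        raise ValueError("n_images must be >= 0")
    if geometry.n_views % factor:
        raise ValueError(f"factor {factor} does not divide {geometry.n_views} views")
    base = spec.seed if seed is None else seed
    triplets = []
    for i in range(n_images):
        p = PhantomSpec(
            size=spec.size,
            n_ellipses=spec.n_ellipses,
            intensity_range=spec.intensity_range,
            seed=base + i,
            wavelet_levels=spec.wavelet_levels,
        )
        img = random_ellipses(p)
        full = radon_forward(img, geometry)
        sparse = subsample_views(full, factor)
        triplets.append((sparse, full, img))
    return triplets


# ---------------------------------------------------------------------------
# I/O: NPY is authoritative; 16-bit PNG previews are rescaled and lossy.


def save_image(path: str | Path, pixels: np.ndarray, png_preview: bool = False) -> None:
    path = Path(path)
    np.save(path.with_suffix(".npy"), np.asarray(pixels, dtype=np.float32))
    if png_preview:
        import imageio.v3 as iio

        arr = np.asarray(pixels, dtype=np.float64)
        lo, hi = arr.min(), arr.max()
        scaled = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
        iio.imwrite(
            path.with_suffix(".png"), (scaled * 65535).astype(np.uint16)
        )


def load_image(path: str | Path) -> np.ndarray:
    return np.load(Path(path).with_suffix(".npy")).astype(np.float64)


def load_dicom(path: str | Path) -> np.ndarray:
    """Read a DICOM slice and min-max normalize its pixel values to [0, 1]."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        arr = np.zeros_like(arr)
    return arr
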