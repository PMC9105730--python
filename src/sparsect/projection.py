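"""Parallel-beam projection, backprojection, and filtered back-projection.

The forward projector discretizes line integrals by marching each ray in
unit steps and spreading every sample over its four neighbouring pixels
with bilinear weights.  The discretization is assembled once per geometry
into a sparse matrix ``A`` (rays x pixels) and cached, so that

* ``radon_forward``   is ``A @ x``,
* ``radon_adjoint``   is ``A.T @ s`` — the *exact* adjoint, as required by
  the algebraic solvers and by backpropagation through the FBP bridge,
* ``fbp``             is ``scale * A.T @ (ramp-filtered s)``.

Because the ramp filter (applied as a circular convolution with an
even-symmetric kernel, zero-padded to a power of two) is self-adjoint,
the gradient of FBP with respect to the sinogram is
``scale * filter(A @ g)`` — computed by :func:`fbp_adjoint` and used as
the analytic backward pass of the differentiable FBP operator.

Geometry convention: views are uniformly spaced over [0°, 360°);
detector count defaults to the image side with one-pixel spacing; rays
beyond the inscribed circle see only zeros (phantom support lives inside
it).  Sinogram layout: rows = detector bins (rays), columns = views.
The sparse-view FBP scale is 2π / n_views / 2, i.e. proportional to the
view spacing, so reconstruction intensity is comparable across
subsampling factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "Geometry",
    "Sinogram",
    "radon_forward",
    "radon_adjoint",
    "fbp",
    "fbp_adjoint",
    "subsample_views",
    "interpolate_views",
    "FILTERS",
]

FILTERS = ("ram-lak", "shepp-logan", "hann")


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam acquisition: uniform view angles over [0°, 360°)."""

    n_views: int
    n_detectors: int
    detector_spacing: float = 1.0
    angles: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_views < 1 or self.n_detectors < 1:
            raise ValueError("n_views and n_detectors must be >= 1")
        if self.angles is None:
            object.__setattr__(
                self,
                "angles",
                tuple(np.arange(self.n_views) * 360.0 / self.n_views),
            )
        else:
            object.__setattr__(self, "angles", tuple(float(a) for a in self.angles))
        a = np.asarray(self.angles)
        if len(a) != self.n_views:
            raise ValueError("angles length must equal n_views")
        if self.n_views > 1:
            d = np.diff(a)
            if np.any(d <= 0) or not np.allclose(d, d[0], atol=1e-9):
                raise ValueError("angles must be strictly increasing and uniform")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.asarray(self.angles)


@dataclass
class Sinogram:
    """Projection data (n_detectors x n_views) bound to its Geometry."""

    values: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("sinogram must be 2D")
        nd, nv = self.values.shape
        if nv != self.geometry.n_views:
            raise ValueError(
                f"column count {nv} != geometry.n_views {self.geometry.n_views}"
            )
        if nd != self.geometry.n_detectors:
            raise ValueError(
                f"row count {nd} != geometry.n_detectors {self.geometry.n_detectors}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")


# ---------------------------------------------------------------------------
# System matrix


_MATRIX_CACHE: dict[tuple, sparse.csr_matrix] = {}
_CACHE_LIMIT = 6


def system_matrix(geometry: Geometry, image_size: int) -> sparse.csr_matrix:
    """Sparse ray-marching projector (n_rays x n_pixels), cached per geometry."""
    key = (geometry.angles, geometry.n_detectors, geometry.detector_spacing, image_size)
    mat = _MATRIX_CACHE.get(key)
    if mat is not None:
        return mat

    n = image_size
    nd = geometry.n_detectors
    center = (n - 1) / 2.0
    det = (np.arange(nd) - (nd - 1) / 2.0) * geometry.detector_spacing
    # unit-step sample positions along each ray, spanning the image
    half = n // 2 + 1
    steps = np.arange(-half, half + 1, dtype=np.float64)

    rows_all, cols_all, vals_all = [], [], []
    for vi, ang in enumerate(geometry.angles_deg):
        phi = np.deg2rad(ang)
        # detector axis u, ray direction w (orthogonal unit vectors)
        ux, uy = np.cos(phi), np.sin(phi)
        wx, wy = -np.sin(phi), np.cos(phi)
        # sample coordinates: (row, col) in image pixel units
        cx = center + det[:, None] * ux + steps[None, :] * wx
        cy = center + det[:, None] * uy + steps[None, :] * wy
        ix = np.floor(cx).astype(np.int64)
        iy = np.floor(cy).astype(np.int64)
        fx = cx - ix
        fy = cy - iy
        ray = np.broadcast_to(
            (vi * nd + np.arange(nd))[:, None], ix.shape
        )
        for dx, dy, w in (
            (0, 0, (1 - fx) * (1 - fy)),
            (1, 0, fx * (1 - fy)),
            (0, 1, (1 - fx) * fy),
            (1, 1, fx * fy),
        ):
            px = ix + dx
            py = iy + dy
            ok = (px >= 0) & (px < n) & (py >= 0) & (py < n) & (w > 0)
            rows_all.append(ray[ok])
            cols_all.append((py[ok] * n + px[ok]).astype(np.int64))
            vals_all.append(w[ok])

    mat = sparse.coo_matrix(
        (
            np.concatenate(vals_all),
            (np.concatenate(rows_all), np.concatenate(cols_all)),
        ),
        shape=(geometry.n_views * nd, n * n),
    ).tocsr()

    if len(_MATRIX_CACHE) >= _CACHE_LIMIT:
        _MATRIX_CACHE.pop(next(iter(_MATRIX_CACHE)))
    _MATRIX_CACHE[key] = mat
    return mat


def radon_forward(image: np.ndarray, geometry: Geometry) -> Sinogram:
    """Discrete line integrals of a square image along parallel rays."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"image must be square 2D, got {image.shape}")
    a = system_matrix(geometry, image.shape[0])
    vals = (a @ image.ravel()).reshape(geometry.n_views, geometry.n_detectors).T
    return Sinogram(vals, geometry)


def radon_adjoint(sinogram: Sinogram, image_size: int | None = None) -> np.ndarray:
    """Unfiltered backprojection: the exact adjoint of :func:`radon_forward`."""
    g = sinogram.geometry
    n = g.n_detectors if image_size is None else image_size
    a = system_matrix(g, n)
    rays = sinogram.values.T.ravel()  # view-major ray ordering
    return (a.T @ rays).reshape(n, n)


# ---------------------------------------------------------------------------
# Ramp filtering


def _ramp_response(pad: int, filter_name: str) -> np.ndarray:
    """Frequency response of the discrete ramp kernel, optionally windowed.

    Real-space kernel (unit detector spacing): h[0] = 1/4,
    h[n] = -1/(pi n)^2 for odd n, 0 for even n; its DFT is real and
    the corresponding circulant is symmetric, so filtering is
    self-adjoint.
    """
    if filter_name not in FILTERS:
        raise ValueError(f"unknown filter {filter_name!r}; choose from {FILTERS}")
    idx = np.fft.fftfreq(pad) * pad  # 0, 1, ..., -1 wrap order
    h = np.zeros(pad)
    h[0] = 0.25
    odd = (np.abs(idx) % 2) == 1
    h[odd] = -1.0 / (np.pi * idx[odd]) ** 2
    response = np.real(np.fft.fft(h))
    if filter_name != "ram-lak":
        freq = np.abs(np.fft.fftfreq(pad))  # cycles/sample in [0, 0.5]
        with np.errstate(invalid="ignore", divide="ignore"):
            if filter_name == "shepp-logan":
                window = np.sinc(freq)  # sin(pi f)/(pi f)
            else:  # hann
                window = 0.5 * (1 + np.cos(2 * np.pi * freq))
        response = response * window
    return response


def _filter_sinogram(values: np.ndarray, filter_name: str) -> np.ndarray:
    nd = values.shape[0]
    pad = max(64, int(2 ** np.ceil(np.log2(2 * nd))))
    response = _ramp_response(pad, filter_name)
    f = np.fft.fft(values, n=pad, axis=0)
    filtered = np.real(np.fft.ifft(f * response[:, None], axis=0))[:nd]
    return filtered


def _fbp_scale(geometry: Geometry) -> float:
    # view spacing in radians over the full circle, halved for the
    # 180-degree redundancy of parallel-beam data
    return (2.0 * np.pi / geometry.n_views) / 2.0


def fbp(
    sinogram: Sinogram,
    filter_name: str = "ram-lak",
    image_size: int | None = None,
) -> np.ndarray:
    """Filtered back-projection; linear in the sinogram."""
    filtered = _filter_sinogram(sinogram.values, filter_name)
    recon = radon_adjoint(
        Sinogram(filtered, sinogram.geometry), image_size=image_size
    )
    return _fbp_scale(sinogram.geometry) * recon


def fbp_adjoint(
    grad_image: np.ndarray, geometry: Geometry, filter_name: str = "ram-lak"
) -> np.ndarray:
    """Adjoint of the FBP map: gradient of FBP output w.r.t. sinogram entries.

    FBP = scale * A^T F with F self-adjoint, so the adjoint is
    scale * F A.  Returns an (n_detectors x n_views) array.
    """
    projected = radon_forward(np.asarray(grad_image), geometry).values
    return _fbp_scale(geometry) * _filter_sinogram(projected, filter_name)


# ---------------------------------------------------------------------------
# View subsampling and angular interpolation


def subsample_views(sinogram: Sinogram, factor: int) -> Sinogram:
    """Keep every ``factor``-th view column, starting at column 0."""
    g = sinogram.geometry
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if g.n_views % factor:
        raise ValueError(f"factor {factor} does not divide n_views {g.n_views}")
    if factor == 1:
        return Sinogram(sinogram.values.copy(), g)
    sub = Geometry(
        n_views=g.n_views // factor,
        n_detectors=g.n_detectors,
        detector_spacing=g.detector_spacing,
        angles=g.angles[::factor],
    )
    return Sinogram(sinogram.values[:, ::factor].copy(), sub)


def interpolate_views(sparse_sino: Sinogram, target: Geometry) -> Sinogram:
    """Linear interpolation along the angle axis with 360° circular wrap.

    Values at the sampled angles are preserved exactly; missing views are
    filled per detector row by periodic linear interpolation.
    """
    src = sparse_sino.geometry
    src_angles = src.angles_deg
    tgt_angles = target.angles_deg
    if src.n_detectors != target.n_detectors:
        raise ValueError("detector counts differ")
    # sampled angles must be a subset of the target's
    if not np.all(
        np.isclose(src_angles[:, None], tgt_angles[None, :], atol=1e-9).any(axis=1)
    ):
        raise ValueError("sparse angles are not a subset of target angles")
    out = np.empty((target.n_detectors, target.n_views))
    for d in range(target.n_detectors):
        out[d] = np.interp(
            tgt_angles, src_angles, sparse_sino.values[d], period=360.0
        )
    # re-impose measured columns exactly (np.interp already does, but keep
    # it bitwise)
    match = np.isclose(tgt_angles[:, None], src_angles[None, :], atol=1e-9)
    for j, i in zip(*np.nonzero(match)):
        out[:, j] = sparse_sino.values[:, i]
    return Sinogram(out, target)
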