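"""Unnormalized 2D Haar wavelet transforms.

The one-level decomposition splits an even-sided image into four
half-resolution subbands with the four +/-1 Haar filters

    f_LL = [[1, 1], [1, 1]]      f_LH = [[-1, -1], [1, 1]]
    f_HL = [[-1, 1], [-1, 1]]    f_HH = [[1, -1], [-1, 1]]

applied to each disjoint 2x2 block (no sqrt normalization: the forward
filters are pure +/-1 sums, the inverse divides by 4).  The transform is
exactly invertible, and because the per-block analysis matrix M satisfies
M M^T = 4 I, subband energy is exactly four times image energy per level.

The wavelet-packet transform recurses into *all four* subbands, giving
4^L equal-size leaves at level L.  ``dwt_stack``/``iwt_stack`` are the
channel-stacked variants used as down/upsampling operators inside the
networks: each channel is transformed independently and the subbands are
concatenated along the channel axis in the fixed order
[CA | CDh | CDv | CDd].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SubbandSet",
    "WPTree",
    "dwt2",
    "iwt2",
    "wpt_decompose",
    "wpt_reconstruct",
    "dwt_stack",
    "iwt_stack",
    "dwt_stack_adjoint",
    "iwt_stack_adjoint",
]


@dataclass
class SubbandSet:
    """One-level Haar subbands: approximation + horizontal/vertical/diagonal detail."""

    CA: np.ndarray
    CDh: np.ndarray
    CDv: np.ndarray
    CDd: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.CA, self.CDh, self.CDv, self.CDd)}
        if len(shapes) != 1:
            raise ValueError(f"subband shapes differ: {shapes}")


@dataclass
class WPTree:
    """Full wavelet-packet tree: 4**level leaves keyed by the filter path.

    ``leaves`` maps path strings like ``"LL.HH"`` (one token per level, in
    order CA='LL', CDh='LH', CDv='HL', CDd='HH') to arrays of shape
    (H/2^L, W/2^L).
    """

    level: int
    leaves: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if len(self.leaves) != 4**self.level:
            raise ValueError(
                f"expected {4 ** self.level} leaves, got {len(self.leaves)}"
            )


def _check_even(x: np.ndarray) -> None:
    if x.ndim < 2:
        raise ValueError("expected at least a 2D array")
    h, w = x.shape[-2], x.shape[-1]
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even, got {h}x{w}")


def _dwt_blocks(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    # 2x2 block corners; works on any (..., H, W) array.
    a = x[..., 0::2, 0::2]  # top-left
    b = x[..., 0::2, 1::2]  # top-right
    c = x[..., 1::2, 0::2]  # bottom-left
    d = x[..., 1::2, 1::2]  # bottom-right
    ca = a + b + c + d
    cdh = -a - b + c + d
    cdv = -a + b - c + d
    cdd = a - b - c + d
    return ca, cdh, cdv, cdd


def _iwt_blocks(
    ca: np.ndarray, cdh: np.ndarray, cdv: np.ndarray, cdd: np.ndarray
) -> np.ndarray:
    shape = ca.shape[:-2] + (2 * ca.shape[-2], 2 * ca.shape[-1])
    x = np.empty(shape, dtype=np.result_type(ca, cdh, cdv, cdd))
    x[..., 0::2, 0::2] = (ca - cdh - cdv + cdd) / 4.0
    x[..., 0::2, 1::2] = (ca - cdh + cdv - cdd) / 4.0
    x[..., 1::2, 0::2] = (ca + cdh - cdv - cdd) / 4.0
    x[..., 1::2, 1::2] = (ca + cdh + cdv + cdd) / 4.0
    return x


def dwt2(image: np.ndarray) -> SubbandSet:
    """One-level unnormalized Haar decomposition of an even-sided 2D array."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("dwt2 expects a 2D array")
    _check_even(image)
    return SubbandSet(*_dwt_blocks(image))


def iwt2(subbands: SubbandSet) -> np.ndarray:
    """Exact inverse of :func:`dwt2`."""
    return _iwt_blocks(subbands.CA, subbands.CDh, subbands.CDv, subbands.CDd)


_PATH_ORDER = ("LL", "LH", "HL", "HH")


def wpt_decompose(image: np.ndarray, level: int) -> WPTree:
    """Full wavelet-packet decomposition: recurse into all four subbands."""
    image = np.asarray(image)
    if level < 1:
        raise ValueError("level must be >= 1")
    h, w = image.shape[-2], image.shape[-1]
    if h % (2**level) or w % (2**level):
        raise ValueError(f"dims {h}x{w} not divisible by 2^{level}")

    leaves: dict[str, np.ndarray] = {"": image}
    for _ in range(level):
        nxt: dict[str, np.ndarray] = {}
        for path, arr in leaves.items():
            subs = _dwt_blocks(arr)
            prefix = path + "." if path else ""
            for token, sub in zip(_PATH_ORDER, subs):
                nxt[prefix + token] = sub
        leaves = nxt
    return WPTree(level=level, leaves=leaves)


def wpt_reconstruct(tree: WPTree) -> np.ndarray:
    """Exact inverse of :func:`wpt_decompose`."""
    leaves = dict(tree.leaves)
    for _ in range(tree.level):
        parents: dict[str, np.ndarray] = {}
        groups: dict[str, dict[str, np.ndarray]] = {}
        for path, arr in leaves.items():
            parent, _, token = path.rpartition(".")
            groups.setdefault(parent, {})[token] = arr
        for parent, subs in groups.items():
            parents[parent] = _iwt_blocks(
                subs["LL"], subs["LH"], subs["HL"], subs["HH"]
            )
        leaves = parents
    return leaves[""]


def dwt_stack(features: np.ndarray) -> np.ndarray:
    """Channel-stacked DWT: (..., C, H, W) -> (..., 4C, H/2, W/2).

    Output channels are the [CA | CDh | CDv | CDd] blocks of the input
    channels, in that frozen order (learned network weights depend on it).
    """
    features = np.asarray(features)
    if features.ndim < 3:
        raise ValueError("dwt_stack expects (..., C, H, W)")
    _check_even(features)
    ca, cdh, cdv, cdd = _dwt_blocks(features)
    return np.concatenate([ca, cdh, cdv, cdd], axis=-3)


def iwt_stack(stacked: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`dwt_stack`: (..., 4C, h, w) -> (..., C, 2h, 2w)."""
    stacked = np.asarray(stacked)
    if stacked.ndim < 3:
        raise ValueError("iwt_stack expects (..., 4C, h, w)")
    c4 = stacked.shape[-3]
    if c4 % 4:
        raise ValueError(f"channel count {c4} not divisible by 4")
    c = c4 // 4
    ca, cdh, cdv, cdd = (
        stacked[..., 0:c, :, :],
        stacked[..., c : 2 * c, :, :],
        stacked[..., 2 * c : 3 * c, :, :],
        stacked[..., 3 * c :, :, :],
    )
    return _iwt_blocks(ca, cdh, cdv, cdd)


# Adjoints of the stacked transforms, used by backpropagation.  With the
# per-block analysis matrix M (rows +/-1, M M^T = 4I) the forward map is
# y = Mx and the inverse is M^-1 = M^T/4, hence adjoint(dwt) = 4*iwt and
# adjoint(iwt) = dwt/4.


def dwt_stack_adjoint(grad_out: np.ndarray) -> np.ndarray:
    return 4.0 * iwt_stack(grad_out)


def iwt_stack_adjoint(grad_out: np.ndarray) -> np.ndarray:
    return 0.25 * dwt_stack(grad_out)
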