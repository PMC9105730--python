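"""Residual restoration networks: MWCNN and its ablations.

All three builders produce encoder-decoder networks that predict the
*artifact residual* of their input; the restored estimate is
``input - predicted residual``.  They differ only in the down/upsampling
operators:

* ``build_mwcnn`` — channel-stacked Haar DWT down, IWT up (lossless,
  invertible: the receptive field grows without discarding information);
* ``build_unet``  — 2x2 max-pool down, 2x2 transposed convolution up;
* ``build_wcnn``  — a single one-level DWT front end with a plain
  convolutional trunk at that one resolution.

Every convolution is 3x3 with one-pixel reflective padding, followed by
batch normalization and ReLU — except the final output convolution,
which is bare.  Encoder and decoder features at equal resolution are
combined by element-wise sum.  With the default spec (3 levels, 4-conv
blocks) the total 3x3-convolution count is exactly 30, asserted by the
builder; transposed convolutions in the U-Net variant are upsamplers and
are not counted as convolution layers.

The final convolution is zero-initialised, so a freshly built model
predicts a zero residual and ``restore`` is the identity map; training
can only move away from that baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor

__all__ = [
    "NetworkSpec",
    "ResidualModel",
    "build_mwcnn",
    "build_wcnn",
    "build_unet",
    "restore",
]


@dataclass
class NetworkSpec:
    """Architecture hyper-parameters shared by all three builders."""

    levels: int = 3
    block_depth: int = 4
    channels: tuple[int, ...] = (64, 128, 256)
    in_channels: int = 1
    downsample: str = "dwt"  # "dwt" | "pool"
    residual: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 1 or self.block_depth < 1:
            raise ValueError("levels and block_depth must be >= 1")
        if len(self.channels) < self.levels:
            raise ValueError("need one channel width per level")
        if self.downsample not in ("dwt", "pool"):
            raise ValueError("downsample must be 'dwt' or 'pool'")


class _ConvUnit:
    """conv3x3 [+ BN + ReLU]."""

    def __init__(self, c_in: int, c_out: int, rng, bare: bool = False, zero: bool = False):
        fan_in = c_in * 9
        if zero:
            w = np.zeros((c_out, c_in, 3, 3), dtype=np.float32)
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, 3, 3)).astype(
                np.float32
            )
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32))
        self.bn = None if bare else ad.BatchNorm2d(c_out)
        self.bare = bare

    def parameters(self):
        ps = [self.weight, self.bias]
        if self.bn is not None:
            ps += self.bn.parameters()
        return ps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        y = ad.conv2d(x, self.weight, self.bias)
        if self.bare:
            return y
        return self.bn(y, training).relu()


class _Upsample:
    """2x2 stride-2 transposed convolution (U-Net decoder)."""

    def __init__(self, c_in: int, c_out: int, rng):
        w = rng.normal(0.0, np.sqrt(2.0 / (c_in * 4)), (c_in, c_out, 2, 2)).astype(
            np.float32
        )
        self.weight = Parameter(w)

    def parameters(self):
        return [self.weight]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return ad.conv_transpose2(x, self.weight)


class ResidualModel:
    """A trained mapping from a degraded input to its artifact residual.

    ``forward`` maps a (N, C, H, W) tensor to a same-shape residual; if the
    spatial dims are not divisible by 2^levels the input is reflectively
    padded and the residual cropped back.
    """

    def __init__(self, spec: NetworkSpec, layers: list, plan: list, conv_count: int):
        self.spec = spec
        self.layers = layers  # flat list of parameterised units
        self.plan = plan  # (op, payload) program executed by forward
        self.conv_count = conv_count

    def parameters(self):
        ps = []
        for unit in self.layers:
            ps += unit.parameters()
        return ps

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        div = 2**self.spec.levels
        n, c, h, w = x.shape
        ph = (-h) % div
        pw = (-w) % div
        t = ad.pad_reflect(x, ph, pw)
        saved: dict[int, Tensor] = {}
        for op, payload in self.plan:
            if op == "unit":
                t = self.layers[payload](t, training)
            elif op == "dwt":
                t = ad.dwt_stack_op(t)
            elif op == "iwt":
                t = ad.iwt_stack_op(t)
            elif op == "pool":
                t = ad.maxpool2(t)
            elif op == "up":
                t = self.layers[payload](t, training)
            elif op == "save":
                saved[payload] = t
            elif op == "sum":
                t = t + saved[payload]
        return ad.crop(t, h, w)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return self.forward(x, training)


def _block(layers, plan, rng, depth, c_in, c_mid, c_out):
    """Append a CNN block: depth convs, first c_in->c_mid, last c_mid->c_out."""
    for k in range(depth):
        ci = c_in if k == 0 else c_mid
        co = c_out if k == depth - 1 else c_mid
        layers.append(_ConvUnit(ci, co, rng))
        plan.append(("unit", len(layers) - 1))


def build_mwcnn(spec: NetworkSpec) -> ResidualModel:
    """Multi-level wavelet CNN: DWT/IWT replace pooling/upsampling.

    Layout (levels L, block depth d): input-lift conv, L encoder blocks
    each followed by a stacked DWT, a bottleneck block whose last conv
    widens for the IWT, then L decoder stages (IWT, element-sum skip,
    block), and a bare zero-initialised output conv.  Total 3x3 convs =
    2 + d*(2L + 1); the default spec gives exactly 30.
    """
    if spec.downsample != "dwt":
        raise ValueError("build_mwcnn requires downsample='dwt'")
    rng = np.random.default_rng(spec.seed)
    ch = spec.channels
    d = spec.block_depth
    L = spec.levels
    layers: list = []
    plan: list = []

    layers.append(_ConvUnit(spec.in_channels, ch[0], rng))  # input lift
    plan.append(("unit", 0))

    # encoder
    for lvl in range(L):
        c_in = ch[0] if lvl == 0 else 4 * ch[lvl - 1]
        _block(layers, plan, rng, d, c_in, ch[lvl], ch[lvl])
        plan.append(("save", lvl))
        plan.append(("dwt", None))

    # bottleneck: last conv widens to 4*ch[L-1] so the IWT lands on ch[L-1]
    _block(layers, plan, rng, d, 4 * ch[L - 1], ch[L - 1], 4 * ch[L - 1])

    # decoder
    for lvl in reversed(range(L)):
        plan.append(("iwt", None))
        plan.append(("sum", lvl))
        c_out = ch[0] if lvl == 0 else 4 * ch[lvl - 1]
        _block(layers, plan, rng, d, ch[lvl], ch[lvl], c_out)

    layers.append(_ConvUnit(ch[0], spec.in_channels, rng, bare=True, zero=True))
    plan.append(("unit", len(layers) - 1))

    n_convs = len(layers)
    expected = 2 + d * (2 * L + 1)
    assert n_convs == expected, f"conv count {n_convs} != {expected}"
    if L == 3 and d == 4:
        assert n_convs == 30, "default MWCNN must contain 30 conv layers"
    return ResidualModel(spec, layers, plan, n_convs)


def build_unet(spec: NetworkSpec) -> ResidualModel:
    """Pooling U-Net ablation: same block topology, max-pool down,
    transposed-conv up.  Conv-layer count matches the MWCNN build."""
    rng = np.random.default_rng(spec.seed)
    ch = spec.channels
    d = spec.block_depth
    L = spec.levels
    layers: list = []
    plan: list = []

    layers.append(_ConvUnit(spec.in_channels, ch[0], rng))
    plan.append(("unit", 0))

    for lvl in range(L):
        c_in = ch[0] if lvl == 0 else ch[lvl - 1]
        _block(layers, plan, rng, d, c_in, ch[lvl], ch[lvl])
        plan.append(("save", lvl))
        plan.append(("pool", None))

    _block(layers, plan, rng, d, ch[L - 1], ch[L - 1], ch[L - 1])

    for lvl in reversed(range(L)):
        layers.append(_Upsample(ch[lvl] if lvl == L - 1 else ch[lvl], ch[lvl], rng))
        plan.append(("up", len(layers) - 1))
        plan.append(("sum", lvl))
        c_out = ch[0] if lvl == 0 else ch[lvl - 1]
        _block(layers, plan, rng, d, ch[lvl], ch[lvl], c_out)

    layers.append(_ConvUnit(ch[0], spec.in_channels, rng, bare=True, zero=True))
    plan.append(("unit", len(layers) - 1))

    n_convs = sum(isinstance(u, _ConvUnit) for u in layers)
    assert n_convs == 2 + d * (2 * L + 1), "U-Net conv count must match MWCNN"
    return ResidualModel(spec, layers, plan, n_convs)


def build_wcnn(spec: NetworkSpec) -> ResidualModel:
    """Single-level wavelet CNN ablation: one DWT front end, a plain
    convolutional trunk at that one (half) resolution, one IWT out.

    The trunk depth is chosen so the conv-layer count equals the MWCNN
    build with the same spec (equal parameter budget per layer count).
    """
    rng = np.random.default_rng(spec.seed)
    ch = spec.channels
    d = spec.block_depth
    L = spec.levels
    total = 2 + d * (2 * L + 1)
    trunk = total - 2 - 2 * d  # head + out + two full-res blocks
    layers: list = []
    plan: list = []

    layers.append(_ConvUnit(spec.in_channels, ch[0], rng))
    plan.append(("unit", 0))
    _block(layers, plan, rng, d, ch[0], ch[0], ch[0])
    plan.append(("save", 0))
    plan.append(("dwt", None))
    # trunk at half resolution, 4x channels in and out for the IWT
    _block(layers, plan, rng, trunk, 4 * ch[0], ch[1], 4 * ch[0])
    plan.append(("iwt", None))
    plan.append(("sum", 0))
    _block(layers, plan, rng, d, ch[0], ch[0], ch[0])
    layers.append(_ConvUnit(ch[0], spec.in_channels, rng, bare=True, zero=True))
    plan.append(("unit", len(layers) - 1))

    model = ResidualModel(spec, layers, plan, total)
    # one-level network: only pad to divisibility by 2
    model.spec = NetworkSpec(
        levels=1,
        block_depth=d,
        channels=ch,
        in_channels=spec.in_channels,
        downsample="dwt",
        residual=spec.residual,
        seed=spec.seed,
    )
    return model


def restore(model: ResidualModel, degraded: np.ndarray) -> np.ndarray:
    """Subtract the predicted artifact residual from a single 2D input."""
    degraded = np.asarray(degraded)
    x = Tensor(degraded[None, None, :, :])
    res = model.forward(x, training=False)
    return (degraded - res.data[0, 0]).astype(np.float64)
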