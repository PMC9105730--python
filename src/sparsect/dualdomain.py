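"""Dual-domain reconstruction: sinogram completion + image restoration.

The hybrid model (DuMWNet-style) chains three stages, trained end-to-end:

1. **RDNet** (radon domain): the sparse-view sinogram is first linearly
   interpolated to the full view grid; a residual MWCNN then predicts the
   interpolation error, giving a completed sinogram.
2. **FBP bridge**: the completed sinogram is reconstructed by filtered
   back-projection.  FBP is linear, so its gradient is its adjoint and
   back-propagation flows through it into RDNet.
3. **IDNet** (image domain): a second residual MWCNN removes the
   remaining artifacts from the FBP image.

The joint loss is the sum of a radon-domain term (completed vs. true
full-view sinogram) and an image-domain term (restored image vs. the FBP
of the true sinogram); both are L2 losses scaled by 1/(2N) over the
batch.  Sinograms are min-max normalized per *dataset* (not per sample)
before entering RDNet — batch normalization wants a fixed physical
scale — and un-normalized again before the FBP bridge.  Measured views
are not re-imposed on the RDNet output by default; pass
``data_consistency=True`` to :func:`reconstruct_dual` for the hard
projection variant.

Passing ``netspec_rd=None`` to :func:`train_dual` trains the
image-domain-only baseline (IDNet on FBP of the interpolated sinogram,
no sinogram network).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .metrics import psnr as _psnr
from .metrics import ssim as _ssim
from .networks import NetworkSpec, ResidualModel, build_mwcnn, build_unet, build_wcnn
from .projection import Geometry, Sinogram, fbp, interpolate_views

__all__ = [
    "TrainSpec",
    "LossReport",
    "l2_residual_loss",
    "joint_loss",
    "train_dual",
    "reconstruct_dual",
    "evaluate",
    "write_csv",
]

_BUILDERS = {"mwcnn": build_mwcnn, "unet": build_unet, "wcnn": build_wcnn}


@dataclass
class TrainSpec:
    """Optimization recipe: Adam(1e-4, 0.9, 0.999), batch 4, x0.9 LR decay
    every 20 epochs."""

    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 4
    lr_decay: float = 0.9
    decay_every: int = 20
    epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("lr > 0, batch_size >= 1, epochs >= 1 required")


@dataclass
class LossReport:
    """Joint-loss breakdown; ``total`` holds the scalar tensor for backward."""

    L_radon: float
    L_image: float
    L_total: float
    total: Tensor | None = field(default=None, repr=False)


def l2_residual_loss(predicted: np.ndarray, target: np.ndarray) -> float:
    """L2 residual loss: (1/2N) sum of squared errors over a batch.

    ``predicted`` and ``target`` are residual-map batches of equal shape
    whose leading axis is the batch axis.
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if predicted.shape != target.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {target.shape}")
    if predicted.shape[0] < 1:
        raise ValueError("batch must contain at least one sample")
    n = predicted.shape[0]
    return float(((predicted - target) ** 2).sum() / (2 * n))


def joint_loss(
    x_sparse: np.ndarray,
    y_full: np.ndarray,
    rdnet: ResidualModel,
    idnet: ResidualModel,
    geometry: Geometry,
    sino_range: tuple[float, float] = (0.0, 1.0),
    training: bool = False,
    radon_weight: float = 1.0,
    image_weight: float = 1.0,
    image_target: np.ndarray | None = None,
) -> LossReport:
    """Joint loss over a paired batch of normalized sinograms.

    ``x_sparse``: interpolated sparse sinograms (N, 1, nd, nv), dataset-
    normalized; ``y_full``: matching true full-view sinograms on the same
    scale.  Gradients of the image term reach RDNet through the FBP
    bridge.  ``radon_weight=0`` probes gradient flow from the image term
    alone.

    The image-domain target defaults to the FBP of the true full-view
    sinogram; pass ``image_target`` (N, 1, H, W) to supply reference
    images instead (at dense-view scale the two coincide, at sparse desk
    scale the full-view FBP is itself artifact-limited).
    """
    x_sparse = np.asarray(x_sparse, dtype=np.float32)
    y_full = np.asarray(y_full, dtype=np.float32)
    if x_sparse.shape != y_full.shape:
        raise ValueError("paired batches must share a shape")
    if x_sparse.shape[-1] != geometry.n_views:
        raise ValueError("batch view count does not match geometry")
    n = x_sparse.shape[0]
    smin, smax = sino_range
    span = smax - smin

    x = Tensor(x_sparse)
    y = Tensor(y_full)
    completed = x - rdnet.forward(x, training=training)
    l_radon = (completed - y).sumsq().scale(radon_weight / (2 * n))

    completed_phys = completed.scale(span).shift(smin)
    img = ad.fbp_bridge(completed_phys, geometry)
    restored = img - idnet.forward(img, training=training)

    if image_target is None:
        # image-domain target: FBP of the true full-view sinogram (no grad)
        y_phys = y_full.astype(np.float64) * span + smin
        ir_y = np.stack(
            [fbp(Sinogram(y_phys[i, 0], geometry)) for i in range(n)]
        )[:, None, :, :]
    else:
        ir_y = np.asarray(image_target, dtype=np.float32)
    l_image = (restored - Tensor(ir_y)).sumsq().scale(image_weight / (2 * n))

    total = l_radon + l_image
    return LossReport(
        L_radon=float(l_radon.data),
        L_image=float(l_image.data),
        L_total=float(total.data),
        total=total,
    )


def _prepare(dataset, geometry_full):
    """Interpolate sparse sinograms onto the full grid; stack arrays."""
    interp, full, images = [], [], []
    for sparse_s, full_s, img in dataset:
        interp.append(interpolate_views(sparse_s, geometry_full).values)
        full.append(full_s.values)
        images.append(np.asarray(img))
    return np.stack(interp), np.stack(full), np.stack(images)


def train_dual(
    dataset,
    netspec_rd: NetworkSpec | None,
    netspec_id: NetworkSpec,
    trainspec: TrainSpec,
    arch: str = "mwcnn",
    valset=None,
    image_target: str = "reference",
) -> tuple[ResidualModel | None, ResidualModel, list[dict]]:
    """Jointly train the sinogram and image networks on phantom triplets.

    ``dataset``: sequence of (sparse Sinogram, full Sinogram, image).
    ``netspec_rd=None`` trains the image-domain-only baseline.  Returns
    (rdnet, idnet, history); history has per-epoch L_radon, L_image and
    validation PSNR.  All randomness (parameter init, shuffling) derives
    from ``trainspec.seed``.

    ``image_target``: "reference" (default) trains the image term toward
    the reference images; "fbp_full" toward the FBP of the true sinogram
    (the two coincide in the dense-view limit).
    """
    if image_target not in ("reference", "fbp_full"):
        raise ValueError("image_target must be 'reference' or 'fbp_full'")
    dataset = list(dataset)
    if not dataset:
        raise ValueError("dataset must not be empty")
    build = _BUILDERS[arch]
    geometry_full = dataset[0][1].geometry
    interp, full, images = _prepare(dataset, geometry_full)

    smin = float(full.min())
    smax = float(full.max())
    span = (smax - smin) or 1.0
    interp_n = ((interp - smin) / span)[:, None].astype(np.float32)
    full_n = ((full - smin) / span)[:, None].astype(np.float32)

    rng = np.random.default_rng(trainspec.seed)
    init_rd = int(rng.integers(2**31))
    init_id = int(rng.integers(2**31))

    rdnet = None
    params = []
    if netspec_rd is not None:
        spec_rd = NetworkSpec(**{**netspec_rd.__dict__, "seed": init_rd})
        rdnet = build(spec_rd)
        params += rdnet.parameters()
    spec_id = NetworkSpec(**{**netspec_id.__dict__, "seed": init_id})
    idnet = build(spec_id)
    params += idnet.parameters()

    if image_target == "reference":
        targets = images[:, None].astype(np.float32)
    else:
        targets = np.stack(
            [fbp(Sinogram(full[i], geometry_full)) for i in range(len(dataset))]
        )[:, None].astype(np.float32)

    # image-only mode: the FBP of the interpolated sinogram is a fixed input
    if rdnet is None:
        fbp_in = np.stack(
            [fbp(Sinogram(interp[i], geometry_full)) for i in range(len(dataset))]
        )[:, None].astype(np.float32)

    opt = Adam(params, lr=trainspec.lr, beta1=trainspec.beta1, beta2=trainspec.beta2)
    history: list[dict] = []
    n_total = len(dataset)
    bs = trainspec.batch_size

    for epoch in range(trainspec.epochs):
        if epoch > 0 and epoch % trainspec.decay_every == 0:
            opt.lr *= trainspec.lr_decay
        order = rng.permutation(n_total)
        ep_radon, ep_image, n_batches = 0.0, 0.0, 0
        for start in range(0, n_total, bs):
            idx = order[start : start + bs]
            opt.zero_grad()
            if rdnet is not None:
                report = joint_loss(
                    interp_n[idx],
                    full_n[idx],
                    rdnet,
                    idnet,
                    geometry_full,
                    sino_range=(smin, smax),
                    training=True,
                    image_target=targets[idx],
                )
                report.total.backward()
                ep_radon += report.L_radon
                ep_image += report.L_image
            else:
                x = Tensor(fbp_in[idx])
                restored = x - idnet.forward(x, training=True)
                loss = (restored - Tensor(targets[idx])).sumsq().scale(
                    1.0 / (2 * len(idx))
                )
                loss.backward()
                ep_image += float(loss.data)
            opt.step()
            n_batches += 1
        entry = {
            "epoch": epoch,
            "L_radon": ep_radon / n_batches,
            "L_image": ep_image / n_batches,
            "L_total": (ep_radon + ep_image) / n_batches,
            "lr": opt.lr,
        }
        if valset:
            scores = [
                _psnr(
                    reconstruct_dual(s, rdnet, idnet, geometry_full, (smin, smax)),
                    np.asarray(img),
                )
                for s, _, img in valset
            ]
            entry["val_psnr"] = float(np.mean(scores))
        history.append(entry)

    if rdnet is not None:
        rdnet.sino_range = (smin, smax)
        rdnet.full_geometry = geometry_full
    idnet.sino_range = (smin, smax)
    idnet.full_geometry = geometry_full
    return rdnet, idnet, history


def reconstruct_dual(
    sparse: Sinogram,
    rdnet: ResidualModel | None,
    idnet: ResidualModel,
    geometry_full: Geometry | None = None,
    sino_range: tuple[float, float] | None = None,
    data_consistency: bool = False,
) -> np.ndarray:
    """Interpolate -> RDNet completion -> FBP -> IDNet restoration."""
    if geometry_full is None:
        geometry_full = getattr(idnet, "full_geometry", None)
    if geometry_full is None:
        raise ValueError("full-view geometry required (train first or pass it)")
    if sino_range is None:
        sino_range = getattr(idnet, "sino_range", (0.0, 1.0))
    smin, smax = sino_range
    span = (smax - smin) or 1.0

    interp = interpolate_views(sparse, geometry_full)
    if rdnet is not None:
        x = Tensor(((interp.values - smin) / span)[None, None].astype(np.float32))
        completed_n = x.data - rdnet.forward(x, training=False).data
        completed = completed_n[0, 0].astype(np.float64) * span + smin
        if data_consistency:
            tgt = geometry_full.angles_deg
            src = sparse.geometry.angles_deg
            match = np.isclose(tgt[:, None], src[None, :], atol=1e-9)
            for j, i in zip(*np.nonzero(match)):
                completed[:, j] = sparse.values[:, i]
        img = fbp(Sinogram(completed, geometry_full))
    else:
        img = fbp(interp)
    xi = Tensor(img[None, None].astype(np.float32))
    restored = xi.data - idnet.forward(xi, training=False).data
    return restored[0, 0].astype(np.float64)


def evaluate(
    methods: dict,
    testsets: dict,
    max_val: float = 1.0,
) -> list[dict]:
    """Mean PSNR/SSIM per (method, subsampling factor).

    ``methods``: name -> callable(sparse Sinogram, reference image) -> image.
    ``testsets``: factor -> list of (sparse, full, image) triplets.
    Returns rows with method, factor, psnr_mean, ssim_mean, n.
    """
    rows = []
    for method, fn in methods.items():
        for factor, triplets in testsets.items():
            ps, ss = [], []
            for sparse_s, _, img in triplets:
                rec = fn(sparse_s, img)
                ps.append(_psnr(rec, img, max_val))
                ss.append(_ssim(rec, img))
            rows.append(
                {
                    "method": method,
                    "factor": factor,
                    "psnr_mean": float(np.mean(ps)),
                    "ssim_mean": float(np.mean(ss)),
                    "n": len(triplets),
                }
            )
    return rows


def write_csv(rows: list[dict], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["method", "factor", "psnr_mean", "ssim_mean", "n"]
        )
        writer.writeheader()
        writer.writerows(rows)
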