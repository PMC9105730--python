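"""Dual-domain model contracts: loss algebra, end-to-end gradient flow
through the FBP bridge, training determinism, and pipeline degeneration
to the Linear+FBP baseline."""

import numpy as np
import pytest

from sparsect.dualdomain import (
    LossReport,
    TrainSpec,
    evaluate,
    joint_loss,
    l2_residual_loss,
    reconstruct_dual,
    train_dual,
)
from sparsect.metrics import psnr
from sparsect.networks import NetworkSpec, build_mwcnn
from sparsect.phantoms import PhantomSpec, make_paired_dataset
from sparsect.projection import Geometry, fbp, interpolate_views

SMALL_NET = NetworkSpec(channels=(4, 6, 8), seed=0)


@pytest.fixture(scope="module")
def tiny_geom():
    return Geometry(n_views=24, n_detectors=16)


@pytest.fixture(scope="module")
def tiny_dataset(tiny_geom):
    spec = PhantomSpec(size=16, wavelet_levels=2, n_ellipses=3, seed=0)
    return make_paired_dataset(8, spec, tiny_geom, factor=6, seed=50)


def tiny_batch(tiny_dataset, tiny_geom, n=2):
    xs, ys = [], []
    for sparse, full, _ in tiny_dataset[:n]:
        xs.append(interpolate_views(sparse, tiny_geom).values)
        ys.append(full.values)
    hi = max(np.max(y) for y in ys) or 1.0
    x = (np.stack(xs) / hi)[:, None].astype(np.float32)
    y = (np.stack(ys) / hi)[:, None].astype(np.float32)
    return x, y, (0.0, float(hi))


class TestL2ResidualLoss:
    def test_zero_for_identical_batches(self, rng):
        r = rng.random((3, 8, 8))
        assert l2_residual_loss(r, r) == 0.0

    def test_single_pixel_off_by_two(self):
        """N=1, one pixel differing by 2 -> (1/2) * 2^2 = 2."""
        p = np.zeros((1, 4, 4))
        t = np.zeros((1, 4, 4))
        p[0, 1, 2] = 2.0
        assert l2_residual_loss(p, t) == pytest.approx(2.0)

    def test_batch_duplication_invariance(self, rng):
        p, t = rng.random((2, 8, 8)), rng.random((2, 8, 8))
        doubled = l2_residual_loss(
            np.concatenate([p, p]), np.concatenate([t, t])
        )
        assert doubled == pytest.approx(l2_residual_loss(p, t))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            l2_residual_loss(np.zeros((1, 4, 4)), np.zeros((1, 4, 5)))


class TestJointLoss:
    def test_perfect_model_fixed_point(self, tiny_dataset, tiny_geom):
        """Fresh residual networks predict zero residuals; feeding the
        true full sinogram as input makes both loss terms vanish."""
        rd = build_mwcnn(SMALL_NET)
        idn = build_mwcnn(SMALL_NET)
        _, y, rng_ = tiny_batch(tiny_dataset, tiny_geom)
        report = joint_loss(y, y, rd, idn, tiny_geom, sino_range=rng_,
                            image_target=None)
        assert report.L_radon == pytest.approx(0.0, abs=1e-8)
        assert report.L_image == pytest.approx(0.0, abs=1e-6)

    def test_additivity(self, tiny_dataset, tiny_geom, rng):
        rd = build_mwcnn(SMALL_NET)
        idn = build_mwcnn(SMALL_NET)
        x, y, rng_ = tiny_batch(tiny_dataset, tiny_geom)
        for _ in range(10):
            xn = np.clip(x + rng.normal(0, 0.02, x.shape), 0, None).astype(
                np.float32
            )
            r = joint_loss(xn, y, rd, idn, tiny_geom, sino_range=rng_)
            assert r.L_total == pytest.approx(r.L_radon + r.L_image, rel=1e-6)
            assert r.L_radon >= 0 and r.L_image >= 0

    def test_image_term_reaches_rdnet_through_bridge(
        self, tiny_dataset, tiny_geom
    ):
        """With the radon term switched off, RDNet still receives nonzero
        gradients — backpropagation crosses the FBP operator."""
        rd = build_mwcnn(SMALL_NET)
        idn = build_mwcnn(SMALL_NET)
        # make RDNet's output depend on its parameters
        rng = np.random.default_rng(4)
        rd.layers[-1].weight.data = rng.normal(
            0, 0.05, rd.layers[-1].weight.data.shape
        ).astype(np.float32)
        x, y, rng_ = tiny_batch(tiny_dataset, tiny_geom)
        report = joint_loss(
            x, y, rd, idn, tiny_geom, sino_range=rng_, radon_weight=0.0
        )
        report.total.backward()
        grads = [p.grad for p in rd.parameters()]
        assert any(g is not None and np.abs(g).max() > 0 for g in grads)

    def test_numerical_gradient_through_whole_chain(
        self, tiny_dataset, tiny_geom
    ):
        """Finite differences on a probed RDNet weight agree with
        backpropagation through completion -> FBP -> restoration."""
        rd = build_mwcnn(SMALL_NET)
        idn = build_mwcnn(SMALL_NET)
        rng = np.random.default_rng(7)
        rd.layers[-1].weight.data = rng.normal(
            0, 0.05, rd.layers[-1].weight.data.shape
        ).astype(np.float32)
        x, y, rng_ = tiny_batch(tiny_dataset, tiny_geom, n=1)

        def value():
            return joint_loss(x, y, rd, idn, tiny_geom, sino_range=rng_).L_total

        report = joint_loss(x, y, rd, idn, tiny_geom, sino_range=rng_)
        report.total.backward()
        # probe the output conv: its gradient sits well above the float32
        # finite-difference noise floor
        w = rd.layers[-1].weight
        eps = 5e-2  # large enough to clear float32 round-off in the FD
        idx = (0, 0, 1, 1)
        orig = w.data[idx]
        w.data[idx] = orig + eps
        lp = value()
        w.data[idx] = orig - eps
        lm = value()
        w.data[idx] = orig
        num = (lp - lm) / (2 * eps)
        assert num == pytest.approx(float(w.grad[idx]), rel=1e-3, abs=1e-6)

    def test_geometry_mismatch_rejected(self, tiny_dataset, tiny_geom):
        rd = build_mwcnn(SMALL_NET)
        idn = build_mwcnn(SMALL_NET)
        x, y, rng_ = tiny_batch(tiny_dataset, tiny_geom)
        wrong = Geometry(n_views=12, n_detectors=16)
        with pytest.raises(ValueError):
            joint_loss(x, y, rd, idn, wrong, sino_range=rng_)


class TestTraining:
    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_dual([], SMALL_NET, SMALL_NET, TrainSpec(epochs=1))

    def test_same_seed_reproduces_first_epoch(self, tiny_dataset):
        """Two runs with one seed agree on the first-epoch loss to 1e-6."""
        h1 = train_dual(
            tiny_dataset, SMALL_NET, SMALL_NET, TrainSpec(epochs=1, seed=11)
        )[2]
        h2 = train_dual(
            tiny_dataset, SMALL_NET, SMALL_NET, TrainSpec(epochs=1, seed=11)
        )[2]
        assert h1[0]["L_total"] == pytest.approx(h2[0]["L_total"], abs=1e-6)

    def test_loss_decreases_over_training(self, tiny_dataset):
        _, _, hist = train_dual(
            tiny_dataset, SMALL_NET, SMALL_NET, TrainSpec(epochs=10, seed=5)
        )
        first = np.mean([h["L_total"] for h in hist[:3]])
        last = np.mean([h["L_total"] for h in hist[-3:]])
        assert last < first

    def test_lr_decay_schedule(self, tiny_dataset):
        spec = TrainSpec(epochs=3, seed=0, decay_every=2, lr_decay=0.5)
        _, _, hist = train_dual(tiny_dataset, SMALL_NET, SMALL_NET, spec)
        assert hist[0]["lr"] == pytest.approx(1e-4)
        assert hist[2]["lr"] == pytest.approx(5e-5)


class TestReconstruct:
    def test_identity_networks_degenerate_to_linear_fbp(
        self, tiny_dataset, tiny_geom
    ):
        """Zero-residual networks make the pipeline exactly the
        interpolate-then-FBP baseline."""
        rd = build_mwcnn(SMALL_NET)
        idn = build_mwcnn(SMALL_NET)
        sparse, full, img = tiny_dataset[0]
        rec = reconstruct_dual(
            sparse, rd, idn, geometry_full=tiny_geom, sino_range=(0.0, 1.0)
        )
        baseline = fbp(interpolate_views(sparse, tiny_geom))
        assert np.abs(rec - baseline).max() < 1e-4
        assert rec.shape == img.shape

    def test_missing_geometry_rejected(self, tiny_dataset):
        rd = build_mwcnn(SMALL_NET)
        idn = build_mwcnn(SMALL_NET)
        with pytest.raises(ValueError):
            reconstruct_dual(tiny_dataset[0][0], rd, idn)


class TestEvaluate:
    def test_ground_truth_scores_perfectly(self, tiny_dataset):
        rows = evaluate(
            {"oracle": lambda s, img: img}, {6: tiny_dataset[:3]}
        )
        assert rows[0]["ssim_mean"] == pytest.approx(1.0)
        assert rows[0]["psnr_mean"] == float("inf")
        assert rows[0]["n"] == 3

    def test_row_count_is_methods_times_factors(self, tiny_dataset, tiny_geom):
        methods = {
            "fbp": lambda s, img: fbp(s),
            "lin": lambda s, img: fbp(interpolate_views(s, tiny_geom)),
        }
        rows = evaluate(methods, {3: tiny_dataset[:2], 6: tiny_dataset[2:4]})
        assert len(rows) == 4

    def test_fbp_quality_falls_with_factor(self, geom_dense, shepp64):
        """Across factors 3 -> 12 the FBP row loses PSNR monotonically."""
        from sparsect.projection import radon_forward, subsample_views

        full = radon_forward(shepp64, geom_dense)
        testsets = {
            f: [(subsample_views(full, f), full, shepp64)] for f in (3, 4, 6, 12)
        }
        rows = evaluate({"fbp": lambda s, img: fbp(s)}, testsets)
        scores = {r["factor"]: r["psnr_mean"] for r in rows}
        assert scores[12] == min(scores.values())
        assert scores[3] == max(scores.values())
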