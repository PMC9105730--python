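# sparsect

Sparse-view CT reconstruction with dual-domain multi-level wavelet
networks, classical baselines, and parallel-beam simulation — on
synthetic phantoms, entirely on CPU.

## The problem

CT reconstruction from angularly undersampled projections is ill-posed:
filtered back-projection (FBP) of a sparse-view sinogram is covered in
directional, globally distributed streaking artifacts. `sparsect`
implements a hybrid-domain learned reconstruction that attacks the
problem in both data domains:

1. **RDNet** — the sparse sinogram is linearly interpolated to the full
   view grid and a residual network predicts the interpolation error,
   completing the sinogram;
2. **FBP bridge** — the completed sinogram is reconstructed by FBP,
   which is linear and therefore differentiable (its gradient is its
   adjoint), so training signal flows backwards through it;
3. **IDNet** — a second residual network removes the remaining artifacts
   in image space.

Both networks are multi-level wavelet CNNs (MWCNN): the encoder replaces
pooling by the channel-stacked Haar DWT and the decoder upsamples by its
exact inverse, enlarging the receptive field without losing information.
The unnormalized Haar subbands of each 2×2 block [[a,b],[c,d]] are

    CA = a+b+c+d,  CDh = −a−b+c+d,  CDv = −a+b−c+d,  CDd = a−b−c+d,

inverted by x = Mᵀy/4. Training minimises the joint loss

    L_total = L_radon + L_image
            = ‖F_radon(x) − y‖² + ‖F_image(IR(F_radon(x))) − target‖²,

where x is the interpolated sparse sinogram, y the full-view sinogram
and IR the FBP operator. One-level-wavelet (WCNN) and pooling (U-Net)
ablations, plus FBP, Linear+FBP, SART and SART-TV baselines, complete
the comparison ladder. The networks run on a small numpy reverse-mode
autodiff engine included in the package; all linear operators
(projection, FBP, wavelets) backpropagate through their analytic
adjoints.

## Worked example

Simulate ten 64² random-ellipse phantoms at 90 full views, keep every
6th view (15 views), and compare classical reconstructions:

```sh
sparsect simulate --size 64 --views 90 --factor 6 --n 10 --seed 11 --out demo
sparsect evaluate --data demo --methods fbp linfbp sarttv --out demo_eval
```

prints

```
     fbp factor 6: PSNR 20.577 dB, SSIM 0.4355 (n=10)
  linfbp factor 6: PSNR 21.007 dB, SSIM 0.6700 (n=10)
  sarttv factor 6: PSNR 30.020 dB, SSIM 0.9368 (n=10)
```

— plain FBP at 15 views is streak-dominated; interpolating the missing
views before FBP helps (especially structurally: SSIM 0.44 → 0.67);
TV-regularized algebraic reconstruction is very strong on these
piecewise-constant phantoms. Training the dual-domain model

```sh
sparsect train --data demo --epochs 20 --seed 1 --out run
sparsect evaluate --data demo --methods fbp dual --checkpoint run/checkpoint.json --out eval2
```

yields a model whose reconstructions beat plain FBP by 2–3 dB after 20
epochs at desk scale (the acceptance suite trains on 100 phantoms and
measures a mean gain of ≈ 2.8 dB on held-out data). A freshly built,
untrained model reproduces the Linear+FBP baseline exactly — the
residual branches are zero-initialised — so training can only improve
on it. In library form:

```python
from sparsect import *

img   = shepp_logan(64)
geom  = Geometry(n_views=360, n_detectors=64)
sino  = radon_forward(img, geom)          # 64 x 360 sinogram
spars = subsample_views(sino, 6)          # 64 x 60, every 6th view
rec   = fbp(spars)                        # streaky reconstruction
print(psnr(rec, img), ssim(rec, img))
```

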