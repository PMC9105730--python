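"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine purpose-built for the restoration networks in
this package: 3x3 convolutions (im2col), batch normalization, ReLU,
element sums, 2x2 max-pooling and transposed convolution, reflective
padding/cropping, the channel-stacked Haar transforms, and the
differentiable FBP bridge.  The wavelet and FBP operators are linear
maps whose backward passes are their analytic adjoints, so no numeric
differentiation is ever involved.

Everything is float32 unless an op says otherwise.  ``Tensor.backward``
runs a topological sweep accumulating ``.grad`` on every tensor with
``requires_grad`` set.
"""

from __future__ import annotations

import numpy as np

from . import wavelet as _wav
from . import projection as _proj

__all__ = ["Tensor", "Parameter", "Adam"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = bwd
        return out

    def __sub__(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data - other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(-g)

        out._backward = bwd
        return out

    def scale(self, alpha: float) -> "Tensor":
        out = Tensor(self.data * np.float32(alpha), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * np.float32(alpha))

        out._backward = bwd
        return out

    def shift(self, beta: float) -> "Tensor":
        out = Tensor(self.data + np.float32(beta), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g)

        out._backward = bwd
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = bwd
        return out

    def sumsq(self) -> "Tensor":
        """Sum of squared entries as a scalar tensor."""
        out = Tensor(np.asarray((self.data.astype(np.float64) ** 2).sum()), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(2.0 * float(g) * self.data)

        out._backward = bwd
        return out


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# Layers / functional ops


def _reflect_pad1(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="reflect")


def _reflect_pad1_adjoint(gp: np.ndarray) -> np.ndarray:
    # fold the pad-1 reflected border back onto its source pixels
    g = gp[:, :, 1:-1, 1:-1].copy()
    g[:, :, 1, :] += gp[:, :, 0, 1:-1]
    g[:, :, -2, :] += gp[:, :, -1, 1:-1]
    g[:, :, :, 1] += gp[:, :, 1:-1, 0]
    g[:, :, :, -2] += gp[:, :, 1:-1, -1]
    g[:, :, 1, 1] += gp[:, :, 0, 0]
    g[:, :, 1, -2] += gp[:, :, 0, -1]
    g[:, :, -2, 1] += gp[:, :, -1, 0]
    g[:, :, -2, -2] += gp[:, :, -1, -1]
    return g


def conv2d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """3x3 convolution, stride 1, one-pixel reflective padding.

    weight: (C_out, C_in, 3, 3); bias: (C_out,).  Computed as nine
    offset-slice batched matmuls, which keeps every copy in natural
    memory order.
    """
    n, c, h, w = x.shape
    co = weight.shape[0]
    xp = _reflect_pad1(x.data)
    # nine shifted views, each copied contiguously: (9, N, C, H*W)
    slices = np.empty((9, n, c, h * w), dtype=np.float32)
    for k in range(9):
        i, j = divmod(k, 3)
        slices[k] = xp[:, :, i : i + h, j : j + w].reshape(n, c, h * w)
    wk = weight.data.reshape(co, c, 9)
    out_flat = np.matmul(wk[:, :, 0], slices[0])
    for k in range(1, 9):
        out_flat += np.matmul(wk[:, :, k], slices[k])
    out_data = out_flat.reshape(n, co, h, w) + bias.data[None, :, None, None]
    out = Tensor(out_data, _prev=(x, weight, bias))

    def bwd(g):
        gm = np.ascontiguousarray(g.reshape(n, co, h * w))
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            # dW[o,c,k] = sum_n gm[n,o,:] @ slices[k,n,c,:]^T
            dw = np.matmul(gm[None], slices.transpose(0, 1, 3, 2)).sum(axis=1)
            weight._accum(dw.transpose(1, 2, 0).reshape(weight.shape))
        if x.requires_grad:
            gp = np.zeros((n, c, h + 2, w + 2), dtype=np.float32)
            for k in range(9):
                i, j = divmod(k, 3)
                gp[:, :, i : i + h, j : j + w] += np.matmul(
                    wk[:, :, k].T, gm
                ).reshape(n, c, h, w)
            x._accum(_reflect_pad1_adjoint(gp))

    out._backward = bwd
    return out


class BatchNorm2d:
    """Batch normalization with running statistics (standard contract)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x.data - mu[None, :, None, None]) / std[None, :, None, None]
        out_data = self.gamma.data[None, :, None, None] * xhat + self.beta.data[
            None, :, None, None
        ]
        gamma, beta = self.gamma, self.beta
        out = Tensor(out_data, _prev=(x, gamma, beta))
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

        def bwd(g):
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gs = gamma.data[None, :, None, None] / std[None, :, None, None]
                if training:
                    mean_g = g.mean(axis=(0, 2, 3), keepdims=True)
                    mean_gx = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
                    x._accum(gs * (g - mean_g - xhat * mean_gx))
                else:
                    x._accum(gs * g)

        out._backward = bwd
        return out


def dwt_stack_op(x: Tensor) -> Tensor:
    out = Tensor(_wav.dwt_stack(x.data), _prev=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(_wav.dwt_stack_adjoint(g).astype(np.float32))

    out._backward = bwd
    return out


def iwt_stack_op(x: Tensor) -> Tensor:
    out = Tensor(_wav.iwt_stack(x.data), _prev=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(_wav.iwt_stack_adjoint(g).astype(np.float32))

    out._backward = bwd
    return out


def maxpool2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, h // 2, w // 2, 4)
    idx = r.argmax(axis=-1)
    out_data = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, _prev=(x,))

    def bwd(g):
        if x.requires_grad:
            gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gr = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accum(gr.reshape(n, c, h, w))

    out._backward = bwd
    return out


def conv_transpose2(x: Tensor, weight: Tensor) -> Tensor:
    """2x2 stride-2 transposed convolution (learned 2x upsampling).

    weight: (C_in, C_out, 2, 2).
    """
    n, c, h, w = x.shape
    co = weight.shape[1]
    t = np.tensordot(x.data, weight.data, axes=([1], [0]))  # (N,H,W,Co,2,2)
    out_data = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, co, 2 * h, 2 * w)
    out = Tensor(out_data, _prev=(x, weight))

    def bwd(g):
        gt = g.reshape(n, co, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)  # (N,H,W,Co,2,2)
        if weight.requires_grad:
            dw = np.einsum("nchw,nhwokl->cokl", x.data, gt, optimize=True)
            weight._accum(dw)
        if x.requires_grad:
            dx = np.einsum("nhwokl,cokl->nchw", gt, weight.data, optimize=True)
            x._accum(dx)

    out._backward = bwd
    return out


def pad_reflect(x: Tensor, pad_h: int, pad_w: int) -> Tensor:
    """Reflective pad on the bottom/right edges (to reach 2^L divisibility)."""
    if pad_h == 0 and pad_w == 0:
        return x
    n, c, h, w = x.shape
    out_data = np.pad(
        x.data, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)), mode="reflect"
    )
    rows = np.concatenate([np.arange(h), h - 2 - np.arange(pad_h)])
    cols = np.concatenate([np.arange(w), w - 2 - np.arange(pad_w)])
    out = Tensor(out_data, _prev=(x,))

    def bwd(g):
        if x.requires_grad:
            dx = np.zeros((n, c, h, w), dtype=np.float32)
            np.add.at(dx, (slice(None), slice(None), rows[:, None], cols[None, :]), g)
            x._accum(dx)

    out._backward = bwd
    return out


def crop(x: Tensor, h: int, w: int) -> Tensor:
    if x.shape[-2] == h and x.shape[-1] == w:
        return x
    out = Tensor(x.data[:, :, :h, :w], _prev=(x,))

    def bwd(g):
        if x.requires_grad:
            gp = np.zeros(x.shape, dtype=np.float32)
            gp[:, :, :h, :w] = g
            x._accum(gp)

    out._backward = bwd
    return out


def fbp_bridge(x: Tensor, geometry, filter_name: str = "ram-lak") -> Tensor:
    """Differentiable FBP applied per batch sample: (N,1,nd,nv) -> (N,1,H,H).

    Linear operator; backward pass is its exact adjoint
    (scale * ramp-filter of the forward projection of the gradient).
    """
    n = x.shape[0]
    size = geometry.n_detectors
    out_data = np.empty((n, 1, size, size), dtype=np.float32)
    for i in range(n):
        sino = _proj.Sinogram(x.data[i, 0].astype(np.float64), geometry)
        out_data[i, 0] = _proj.fbp(sino, filter_name)
    out = Tensor(out_data, _prev=(x,))

    def bwd(g):
        if x.requires_grad:
            dx = np.empty(x.shape, dtype=np.float32)
            for i in range(n):
                dx[i, 0] = _proj.fbp_adjoint(
                    g[i, 0].astype(np.float64), geometry, filter_name
                )
            x._accum(dx)

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Optimizer


class Adam:
    """Adam with the training recipe's defaults: alpha=1e-4, betas=(0.9, 0.999)."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
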