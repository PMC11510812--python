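"""Minimal numpy implementation of a 2-D U-Net with Adam training.

Implemented from scratch (no deep-learning framework is required at run
time): 3x3 "same" convolutions via im2col matrix products, batch
normalisation, ReLU, 2x2 max pooling, nearest-neighbour upsampling with a
post-convolution, skip concatenation, and a 1x1 output convolution.  All
parameters are float32; given a fixed seed, initialisation and training are
bit-reproducible on one machine.

The network is deliberately small: the denoiser operates on 16x16 spatial
blocks whose energy depth maps onto the convolution channel axis.
"""

from __future__ import annotations

import numpy as np

__all__ = ["UNet2d", "Adam", "mse_loss"]


def _im2col(x: np.ndarray, k: int, pad: int):
    """x (N, C, H, W) -> columns (N, C*k*k, H*W) for 'same' convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k * k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i * k + j] = xp[:, :, i : i + h, j : j + w]
    return cols.reshape(n, c * k * k, h * w)


def _col2im(dcols: np.ndarray, shape, k: int, pad: int):
    """Adjoint of _im2col: scatter-add column gradients back to the image."""
    n, c, h, w = shape
    d = dcols.reshape(n, c, k * k, h, w)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + h, j : j + w] += d[:, :, i * k + j]
    return xp[:, :, pad : pad + h, pad : pad + w] if pad else xp


class Conv2d:
    def __init__(self, rng, c_in: int, c_out: int, k: int = 3):
        std = np.sqrt(2.0 / (c_in * k * k))  # He initialisation
        self.w = (rng.standard_normal((c_out, c_in * k * k)) * std).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k, self.pad, self.c_in = k, k // 2, c_in
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x, training):
        self._shape = x.shape
        self._cols = _im2col(x, self.k, self.pad)
        n, _, hw = self._cols.shape
        out = np.einsum("ok,nkh->noh", self.w, self._cols) + self.b[None, :, None]
        h, w = x.shape[2], x.shape[3]
        return out.reshape(n, -1, h, w)

    def backward(self, g):
        n, co, h, w = g.shape
        g2 = g.reshape(n, co, h * w)
        self.gw[...] = np.einsum("noh,nkh->ok", g2, self._cols)
        self.gb[...] = g2.sum(axis=(0, 2))
        dcols = np.einsum("ok,noh->nkh", self.w, g2)
        self._cols = None
        return _col2im(dcols, self._shape, self.k, self.pad)


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self._xhat = (x - mean[None, :, None, None]) * self._invstd[None, :, None, None]
        self._training = training
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, g):
        xhat = self._xhat
        self.ggamma[...] = (g * xhat).sum(axis=(0, 2, 3))
        self.gbeta[...] = g.sum(axis=(0, 2, 3))
        if not self._training:
            return g * (self.gamma * self._invstd)[None, :, None, None]
        m = g.shape[0] * g.shape[2] * g.shape[3]
        gxhat = g * self.gamma[None, :, None, None]
        term = (
            gxhat
            - gxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        )
        self._xhat = None
        return term * self._invstd[None, :, None, None]


class ReLU:
    def params(self):
        return []

    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool2:
    def params(self):
        return []

    def forward(self, x, training):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xv = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xv.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(xv, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        n, c, h, w = self._inshape
        gv = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(gv, self._idx[..., None], g[..., None], axis=-1)
        gr = gv.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return gr.reshape(n, c, h, w)


class Upsample2:
    def params(self):
        return []

    def forward(self, x, training):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, g):
        n, c, h, w = g.shape
        return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class _Sequential:
    def __init__(self, layers):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


def _double_conv(rng, c_in, c_out):
    return _Sequential(
        [
            Conv2d(rng, c_in, c_out),
            BatchNorm2d(c_out),
            ReLU(),
            Conv2d(rng, c_out, c_out),
            BatchNorm2d(c_out),
            ReLU(),
        ]
    )


class UNet2d:
    """Three-level (or ``depth``-level) U-Net with skip concatenations."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        base_channels: int = 32,
        depth: int = 3,
        seed: int = 0,
    ):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        rng = np.random.default_rng(seed)
        widths = [base_channels * 2**i for i in range(depth)]
        self.depth = depth
        self.enc = []
        c_prev = in_channels
        for c in widths[:-1]:
            self.enc.append(_double_conv(rng, c_prev, c))
            c_prev = c
        self.pools = [MaxPool2() for _ in widths[:-1]]
        self.bottleneck = _double_conv(rng, c_prev, widths[-1])
        self.ups = []
        self.up_convs = []
        self.dec = []
        for i in reversed(range(depth - 1)):
            self.ups.append(Upsample2())
            self.up_convs.append(Conv2d(rng, widths[i + 1], widths[i]))
            self.dec.append(_double_conv(rng, 2 * widths[i], widths[i]))
        self.out_conv = Conv2d(rng, widths[0], out_channels, k=1)
        self._widths = widths

    def params(self):
        out = []
        for block in self.enc:
            out += block.params()
        out += self.bottleneck.params()
        for up_conv, dec in zip(self.up_convs, self.dec):
            out += up_conv.params()
            out += dec.params()
        out += self.out_conv.params()
        return out

    def forward(self, x, training: bool = False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bottleneck.forward(x, training)
        self._skip_channels = []
        for up, up_conv, dec, skip in zip(
            self.ups, self.up_convs, self.dec, reversed(skips)
        ):
            x = up.forward(x, training)
            x = up_conv.forward(x, training)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, training)
        return self.out_conv.forward(x, training)

    def backward(self, g):
        g = self.out_conv.backward(g)
        skip_grads = []
        for dec, up_conv, up, c_skip in zip(
            reversed(self.dec),
            reversed(self.up_convs),
            reversed(self.ups),
            reversed(self._skip_channels),
        ):
            g = dec.backward(g)
            skip_grads.append(g[:, :c_skip])
            g = up.backward(up_conv.backward(g[:, c_skip:]))
        g = self.bottleneck.backward(g)
        for block, pool, gs in zip(
            reversed(self.enc), reversed(self.pools), reversed(skip_grads)
        ):
            g = pool.backward(g) + gs
            g = block.backward(g)
        return g

    # --------------------------------------------------------- persistence
    def state_dict(self) -> dict:
        state = {}
        for i, (p, _) in enumerate(self.params()):
            state[f"param_{i}"] = p
        bn = [
            layer
            for block in (
                self.enc + [self.bottleneck] + self.dec
            )
            for layer in block.layers
            if isinstance(layer, BatchNorm2d)
        ]
        for i, layer in enumerate(bn):
            state[f"bn_mean_{i}"] = layer.running_mean
            state[f"bn_var_{i}"] = layer.running_var
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, (p, _) in enumerate(self.params()):
            p[...] = state[f"param_{i}"]
        bn = [
            layer
            for block in (self.enc + [self.bottleneck] + self.dec)
            for layer in block.layers
            if isinstance(layer, BatchNorm2d)
        ]
        for i, layer in enumerate(bn):
            layer.running_mean[...] = state[f"bn_mean_{i}"]
            layer.running_var[...] = state[f"bn_var_{i}"]


class Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mse_loss(pred, target):
    """Mean squared error and its gradient w.r.t. pred."""
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 / diff.size) * diff
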