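"""Minimal NumPy neural-network layers with explicit backpropagation.

Implements exactly the operations the 2D U-Net needs — 3x3/1x1
convolutions (im2col), batch normalisation, ReLU, 2x2 max pooling, 2x2
stride-2 transposed convolution, channel concatenation — plus MSE loss and
an Adam optimiser. Tensors are ``(N, C, H, W)`` float32 throughout. Layers
cache activations only when called with ``training=True``, so inference on
large slices stays memory-light. All randomness flows through an explicit
``numpy.random.Generator``, making training bit-reproducible for a given
seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: parameters in ``params``, gradients in ``grads``."""

    def __init__(self):
        self.params: dict = {}
        self.grads: dict = {}
        self.cache = None

    def forward(self, x, training: bool = True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """Stride-1 2D convolution with 'same' padding, He-normal init."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, ksize
        self.pad = ksize // 2
        scale = np.sqrt(2.0 / (cin * ksize * ksize))
        self.params["W"] = rng.normal(0.0, scale, (cout, cin, ksize, ksize)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    @staticmethod
    def _im2col(x, k, pad):
        n, c, h, w = x.shape
        if pad:
            x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        cols = sliding_window_view(x, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
        return np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * k * k
        )

    def forward(self, x, training: bool = True):
        n, c, h, w = x.shape
        cols = self._im2col(x, self.k, self.pad)
        wmat = self.params["W"].reshape(self.cout, -1).T  # (C*k*k, F)
        out = cols @ wmat + self.params["b"]
        out = out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)
        self.cache = (cols, x.shape) if training else None
        return np.ascontiguousarray(out)

    def backward(self, dout):
        cols, xshape = self.cache
        n, c, h, w = xshape
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.grads["W"] = (dmat.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"] = dmat.sum(axis=0)
        # dx = full correlation of dout with the spatially-flipped kernel
        wflip = self.params["W"][:, :, ::-1, ::-1].transpose(0, 2, 3, 1)  # (F,k,k,C)
        wmat = np.ascontiguousarray(wflip).reshape(self.cout * self.k * self.k, c)
        dcols = self._im2col(dout, self.k, self.k - 1 - self.pad if self.k > 1 else 0)
        dx = (dcols @ wmat).reshape(n, h, w, c)  # dtype follows the inputs
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class BatchNorm2d(Layer):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x, training: bool = True):
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * invstd[None, :, None, None]
        out = xhat * self.params["gamma"][None, :, None, None] + self.params["beta"][None, :, None, None]
        self.cache = (xhat, invstd) if training else None
        return out.astype(x.dtype)

    def backward(self, dout):
        xhat, invstd = self.cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.params["gamma"][None, :, None, None]
        # standard batch-norm backward, vectorised per channel
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (invstd[None, :, None, None] / m) * (
            m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat
        )
        return dx.astype(xhat.dtype)


class ReLU(Layer):
    def forward(self, x, training: bool = True):
        out = np.maximum(x, 0)
        self.cache = (x > 0) if training else None
        return out

    def backward(self, dout):
        return dout * self.cache


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; gradient routed to the unique argmax."""

    def forward(self, x, training: bool = True):
        n, c, h, w = x.shape
        x6 = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = x6.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self.cache = (idx, x.shape) if training else None
        return np.ascontiguousarray(out)

    def backward(self, dout):
        idx, (n, c, h, w) = self.cache
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx.reshape(n, c, h, w))


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout = cin, cout
        scale = np.sqrt(2.0 / (cin * 4))
        self.params["W"] = rng.normal(0.0, scale, (cin, cout, 2, 2)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    def forward(self, x, training: bool = True):
        n, c, h, w = x.shape
        out6 = np.einsum("ncij,cfpq->nfipjq", x, self.params["W"], optimize=True)
        out = out6.reshape(n, self.cout, 2 * h, 2 * w) + self.params["b"][None, :, None, None]
        self.cache = x if training else None
        return np.ascontiguousarray(out)

    def backward(self, dout):
        x = self.cache
        n, c, h, w = x.shape
        d6 = dout.reshape(n, self.cout, h, 2, w, 2).transpose(0, 1, 2, 4, 3, 5)
        self.grads["W"] = np.einsum("ncij,nfijpq->cfpq", x, d6, optimize=True)
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        dx = np.einsum("nfijpq,cfpq->ncij", d6, self.params["W"], optimize=True)
        return np.ascontiguousarray(dx)


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, training: bool = True):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def conv_bn_relu(cin, cout, rng) -> Sequential:
    """ConvBNReLU block: 3x3 conv -> batch norm -> ReLU."""
    return Sequential(Conv2d(cin, cout, 3, rng), BatchNorm2d(cout), ReLU())


def unet_conv_block(cin, cout, rng) -> Sequential:
    """UnetConv2D block: two consecutive ConvBNReLU blocks."""
    return Sequential(conv_bn_relu(cin, cout, rng), conv_bn_relu(cout, cout, rng))


def iter_param_layers(layer):
    """Yield every layer that owns parameters, depth-first."""
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from iter_param_layers(sub)
    elif layer.params:
        yield layer


class MSELoss:
    """Mean squared error over all elements."""

    def forward(self, pred, target):
        self.diff = pred - target
        return float(np.mean(self.diff ** 2))

    def backward(self):
        return (2.0 / self.diff.size) * self.diff.astype(np.float32)


class Adam:
    """Adam with the conventional default moments (0.9, 0.999)."""

    def __init__(self, layers, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for root in layers for l in iter_param_layers(root)]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for key, p in layer.params.items():
                g = layer.grads[key]
                m[key] = self.beta1 * m[key] + (1 - self.beta1) * g
                v[key] = self.beta2 * v[key] + (1 - self.beta2) * g * g
                mhat = m[key] / b1t
                vhat = v[key] / b2t
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


class UNet:
    """2D U-Net: 4 down-sampling blocks, a bottleneck, 4 up-sampling blocks.

    Encoder blocks are ``UnetConv2D -> 2x2 max pool``; the bottleneck is a
    single UnetConv2D; decoder blocks are ``2x2 transposed conv ->
    concatenate skip -> UnetConv2D``; a final 1x1 convolution maps to the
    output channel. Input height/width must be divisible by
    ``2**len(encoder_channels)``.
    """

    def __init__(self, in_channels: int = 1, out_channels: int = 1,
                 encoder_channels=(32, 64, 128, 256), bottleneck_channels: int = 512,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoder_channels = tuple(encoder_channels)
        self.bottleneck_channels = int(bottleneck_channels)
        self.in_channels, self.out_channels = in_channels, out_channels
        self.depth = len(self.encoder_channels)

        self.enc_blocks, self.pools = [], []
        cin = in_channels
        for cout in self.encoder_channels:
            self.enc_blocks.append(unet_conv_block(cin, cout, rng))
            self.pools.append(MaxPool2d())
            cin = cout
        self.center = unet_conv_block(cin, bottleneck_channels, rng)
        self.upconvs, self.dec_blocks = [], []
        cin = bottleneck_channels
        for skip_ch in reversed(self.encoder_channels):
            self.upconvs.append(ConvTranspose2d(cin, skip_ch, rng))
            self.dec_blocks.append(unet_conv_block(2 * skip_ch, skip_ch, rng))
            cin = skip_ch
        self.final = Conv2d(cin, out_channels, 1, rng)
        # near-zero output head: training starts from a flat prediction and
        # builds the mapping up, which removes the strong dependence of the
        # optimisation path on the head's random draw
        self.final.params["W"] *= np.float32(0.01)

    # -- execution ------------------------------------------------------

    def _check_divisible(self, x):
        h, w = x.shape[-2:]
        div = 2 ** self.depth
        if h % div or w % div:
            raise ValueError(f"input spatial dims {h}x{w} must be divisible by {div}")

    def forward(self, x, training: bool = True):
        self._check_divisible(x)
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            x = block.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.center.forward(x, training)
        self._skip_channels = []
        for up, dec, skip in zip(self.upconvs, self.dec_blocks, reversed(skips)):
            x = up.forward(x, training)
            x = np.concatenate([skip, x], axis=1)
            self._skip_channels.append(skip.shape[1])
            x = dec.forward(x, training)
        return self.final.forward(x, training)

    def backward(self, dout):
        dout = self.final.backward(dout)
        dskips = []
        for up, dec, nskip in zip(reversed(self.upconvs), reversed(self.dec_blocks),
                                  reversed(self._skip_channels)):
            d = dec.backward(dout)
            dskips.append(d[:, :nskip])
            dout = up.backward(d[:, nskip:])
        dout = self.center.backward(dout)
        # dskips was collected shallow-first; the encoder unwinds deep-first
        for pool, block, dskip in zip(reversed(self.pools), reversed(self.enc_blocks),
                                      reversed(dskips)):
            d = pool.backward(dout)
            dout = block.backward(d + dskip)
        return dout

    # -- bookkeeping ----------------------------------------------------

    def roots(self):
        return self.enc_blocks + [self.center] + self.upconvs + self.dec_blocks + [self.final]

    def param_layers(self):
        for root in self.roots():
            yield from iter_param_layers(root)

    def param_count(self) -> int:
        return sum(p.size for l in self.param_layers() for p in l.params.values())

    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.param_layers()):
            for key, val in layer.params.items():
                state[f"{i}.{key}"] = val.copy()
            if isinstance(layer, BatchNorm2d):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.param_layers()):
            for key in layer.params:
                layer.params[key][...] = state[f"{i}.{key}"]
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"{i}.running_mean"]
                layer.running_var[...] = state[f"{i}.running_var"]
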