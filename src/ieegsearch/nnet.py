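"""A compact numpy convolutional network with hand-written backprop.

The embedding and classification networks in this package are small
(a few convolution blocks on a downsampled spectrogram image), so forward
and backward passes are implemented directly on numpy arrays in NCHW
layout using im2col convolutions. Everything is deterministic given the
initialization seed: there is no dropout, no batch statistics, and
weights are drawn from a seeded generator with He-style scaling.

Layers expose ``forward(x)`` / ``backward(grad)`` plus ``params`` and
``grads`` lists; :class:`Adam` updates the parameters in place.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution via im2col; 'same'-style zero padding."""

    def __init__(self, in_ch, out_ch, k=3, stride=1, pad=1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        w = rng.standard_normal((out_ch, in_ch, k, k)) * np.sqrt(2.0 / fan_in)
        b = np.zeros(out_ch)
        self.k, self.stride, self.pad = k, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params = [w.astype(np.float64), b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self._cache = None

    def _im2col(self, x):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (n, c, ho, wo, k, k)
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        return cols, (n, ho, wo, xp.shape[2], xp.shape[3])

    def forward(self, x):
        w, b = self.params
        cols, (n, ho, wo, hp, wp) = self._im2col(x)
        out = cols @ w.reshape(self.out_ch, -1).T + b
        self._cache = (cols, x.shape, (n, ho, wo, hp, wp))
        return out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad):
        w, _ = self.params
        cols, x_shape, (n, ho, wo, hp, wp) = self._cache
        g = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.out_ch)
        self.grads[0][...] = (g.T @ cols).reshape(w.shape)
        self.grads[1][...] = g.sum(axis=0)
        dcols = g @ w.reshape(self.out_ch, -1)
        dcols = dcols.reshape(n, ho, wo, self.in_ch, self.k, self.k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (n, c, ho, wo, k, k)
        dxp = np.zeros((n, self.in_ch, hp, wp))
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ]
        p = self.pad
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class AvgPool2d(Layer):
    """Non-overlapping average pooling by an integer factor (no params)."""

    def __init__(self, factor: int):
        super().__init__()
        self.f = factor

    def forward(self, x):
        n, c, h, w = x.shape
        f = self.f
        if h % f or w % f:
            raise ParameterError(f"spatial dims {h}x{w} not divisible by {f}")
        self._in_shape = x.shape
        return x.reshape(n, c, h // f, f, w // f, f).mean(axis=(3, 5))

    def backward(self, grad):
        f = self.f
        g = grad / (f * f)
        return np.repeat(np.repeat(g, f, axis=2), f, axis=3)


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._in_shape
        return np.broadcast_to(
            grad[:, :, None, None] / (h * w), self._in_shape
        ).copy()


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        b = np.zeros(n_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x):
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, grad):
        w, _ = self.params
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ w.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -np.log(probs[np.arange(n), labels] + 1e-12).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


# ---------------------------------------------------------------------------
# network builders

#: (out_channels, stride) per conv block of the desk-scale trunk; each block
#: halves the spatial extent, taking the 4x-downsampled 56x56 input to 7x7.
TRUNK_BLOCKS = ((16, 2), (32, 2), (64, 2))
INPUT_DOWNSAMPLE = 4


def build_trunk(seed: int, n_blocks: int | None = None) -> tuple[Sequential, int]:
    """Convolutional trunk mapping a 3 x 224 x 224 image to a feature map.

    Returns the network and its output channel count. ``n_blocks`` < 3
    truncates blocks from the end, yielding a spatially larger, shallower
    map.
    """
    blocks = TRUNK_BLOCKS if n_blocks is None else TRUNK_BLOCKS[:n_blocks]
    if not blocks:
        raise ParameterError("trunk needs at least one conv block")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7B]))
    layers: list[Layer] = [AvgPool2d(INPUT_DOWNSAMPLE)]
    in_ch = 3
    for out_ch, stride in blocks:
        layers.append(Conv2d(in_ch, out_ch, k=3, stride=stride, pad=1, rng=rng))
        layers.append(ReLU())
        in_ch = out_ch
    return Sequential(layers), in_ch


def images_to_batch(images) -> np.ndarray:
    """Stack (H, W, 3) images in [0, 1] into an NCHW float batch."""
    arr = np.stack([np.asarray(im, dtype=np.float64) for im in images])
    return arr.transpose(0, 3, 1, 2)
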