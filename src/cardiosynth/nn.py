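"""Minimal neural-network layer stack on numpy.

Layers operate on NCHW float32 tensors and implement explicit forward/backward
passes; gradients are accumulated on each layer's parameter objects and applied
by the Adam optimizer below.  The stack covers exactly the operators needed by
the progressive GAN and the U-Net: stride-1 convolutions (via im2col and BLAS
matmul), nearest-neighbor upsampling, 2x2 average/max pooling, leaky ReLU,
pixelwise feature normalization, the minibatch-standard-deviation channel, and
dense layers.  Everything is deterministic given the seeds handed to the
initializers.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ShapeMismatchError

DTYPE = np.float32


class Parameter:
    """A trainable array with an accumulated gradient (None when untouched)."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad: np.ndarray | None = None

    def add_grad(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g.astype(DTYPE, copy=False)


class Layer:
    """Base layer; subclasses cache whatever backward needs."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def he_init(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


# ---------------------------------------------------------------------------
# convolution


def _im2col(x: np.ndarray, kh: int, kw: int,
            pad: tuple[int, int, int, int]) -> np.ndarray:
    """(N,C,H,W) -> (N, Ho*Wo, C*kh*kw) patch matrix for stride-1 convolution."""
    pt, pb, pl, pr = pad
    if any(pad):
        x = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # N,C,Ho,Wo,kh,kw
    n, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), (ho, wo)


#: symmetric/asymmetric same-padding per kernel size (stride 1)
_SAME_PAD = {1: (0, 0, 0, 0), 2: (0, 1, 0, 1), 3: (1, 1, 1, 1)}


class Conv2d(Layer):
    """Stride-1 2-D convolution with same-padding for kernel sizes 1, 2, 3.

    With ``eq_lr`` the weights are stored at unit scale and multiplied by the
    He constant at run time (equalized learning rate), which equalizes the
    effective per-layer step size under Adam.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, gain: float = 1.0,
                 eq_lr: bool = False):
        if kernel not in _SAME_PAD:
            raise ValueError(f"unsupported kernel size {kernel}")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        self.pad = _SAME_PAD[kernel]
        fan_in = in_channels * kernel * kernel
        if eq_lr:
            self.scale = DTYPE(gain * np.sqrt(2.0 / fan_in))
            self.W = Parameter(rng.normal(0.0, 1.0, (out_channels, fan_in)))
        else:
            self.scale = DTYPE(1.0)
            self.W = Parameter(gain * he_init(rng, (out_channels, fan_in),
                                              fan_in))
        self.b = Parameter(np.zeros(out_channels))
        self._cache = None

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        cols, (ho, wo) = _im2col(x, self.k, self.k, self.pad)
        y = cols @ (self.scale * self.W.value).T + self.b.value
        self._cache = (cols, x.shape, (ho, wo))
        return y.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, (ho, wo) = self._cache
        n = dy.shape[0]
        dymat = dy.transpose(0, 2, 3, 1).reshape(n, ho * wo, self.cout)
        self.W.add_grad(self.scale *
                        np.tensordot(dymat, cols, axes=([0, 1], [0, 1])))
        self.b.add_grad(dymat.sum(axis=(0, 1)))
        # gradient w.r.t. input: full correlation with the flipped kernel
        k = self.k
        wmat = (self.scale * self.W.value).reshape(self.cout, self.cin, k, k)
        wflip = wmat[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(
            self.cin, self.cout * k * k)
        pt, pb, pl, pr = self.pad
        dpad = (k - 1 - pt, k - 1 - pb, k - 1 - pl, k - 1 - pr)
        dcols, (h, w) = _im2col(dymat.reshape(n, ho, wo, self.cout)
                                .transpose(0, 3, 1, 2), k, k, dpad)
        dx = (dcols @ wflip.T).reshape(n, h, w, self.cin).transpose(0, 3, 1, 2)
        assert dx.shape == x_shape
        return np.ascontiguousarray(dx)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 gain: float = 1.0, eq_lr: bool = False):
        if eq_lr:
            self.scale = DTYPE(gain * np.sqrt(2.0 / n_in))
            self.W = Parameter(rng.normal(0.0, 1.0, (n_out, n_in)))
        else:
            self.scale = DTYPE(1.0)
            self.W = Parameter(gain * he_init(rng, (n_out, n_in), n_in))
        self.b = Parameter(np.zeros(n_out))
        self._x = None

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ (self.scale * self.W.value).T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.add_grad(self.scale * (dy.T @ self._x))
        self.b.add_grad(dy.sum(axis=0))
        return dy @ (self.scale * self.W.value)


# ---------------------------------------------------------------------------
# activations and structural ops


class LeakyReLU(Layer):
    def __init__(self, leakiness: float = 0.2):
        self.a = leakiness
        self._mask = None

    def forward(self, x):
        self._mask = x >= 0
        return np.where(self._mask, x, self.a * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.a * dy)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(0.0)


class Upsample2x(Layer):
    """Nearest-neighbor 2x upscaling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class AvgPool2x(Layer):
    def forward(self, x):
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy):
        return dy.repeat(2, axis=2).repeat(2, axis=3) * DTYPE(0.25)


class MaxPool2x(Layer):
    def forward(self, x):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = r.reshape(n, c, h // 2, w // 2, 4)
        self._idx = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy):
        n, c, h, w = self._in_shape
        onehot = np.eye(4, dtype=DTYPE)[self._idx]          # n,c,h/2,w/2,4
        flat = onehot * dy[..., None]
        r = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return r.reshape(n, c, h, w)


def avgpool2x(x: np.ndarray) -> np.ndarray:
    """Functional 2x2 average pooling (no gradient)."""
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def upsample2x(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


# ---------------------------------------------------------------------------
# GAN stabilization operators


def pixelwise_feature_norm(x: np.ndarray, epsilon: float = 1e-8) -> np.ndarray:
    """Normalize each spatial position's channel vector to unit mean square.

    x has shape (N, C, H, W); returns x / sqrt(mean_c(x^2) + epsilon).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    ms = np.mean(np.square(x), axis=1, keepdims=True)
    return x / np.sqrt(ms + epsilon)


class PixelNorm(Layer):
    def __init__(self, epsilon: float = 1e-8):
        self.eps = epsilon
        self._cache = None

    def forward(self, x):
        ms = np.mean(np.square(x), axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(ms + self.eps)
        y = x * inv
        self._cache = (x, inv)
        return y.astype(DTYPE, copy=False)

    def backward(self, dy):
        x, inv = self._cache
        c = x.shape[1]
        dot = np.sum(dy * x, axis=1, keepdims=True)
        return (dy * inv - x * (dot * inv ** 3 / c)).astype(DTYPE, copy=False)


def minibatch_stddev_channel(x: np.ndarray, epsilon: float = 1e-8) -> np.ndarray:
    """Append the across-batch variability channel used by the critic.

    The appended channel is a single scalar broadcast over batch and space: the
    mean over all features (channel x position) of the per-feature population
    standard deviation across the batch.
    """
    sd = np.sqrt(np.var(x, axis=0) + epsilon)
    stat = sd.mean()
    extra = np.full((x.shape[0], 1) + x.shape[2:], stat, dtype=x.dtype)
    return np.concatenate([x, extra], axis=1)


class MinibatchStdDev(Layer):
    def __init__(self, epsilon: float = 1e-8):
        self.eps = epsilon
        self._cache = None

    def forward(self, x):
        mean = x.mean(axis=0, keepdims=True)
        var = np.var(x, axis=0)
        sd = np.sqrt(var + self.eps)
        stat = sd.mean()
        self._cache = (x, mean, sd)
        extra = np.full((x.shape[0], 1) + x.shape[2:], stat, dtype=x.dtype)
        return np.concatenate([x, extra], axis=1)

    def backward(self, dy):
        x, mean, sd = self._cache
        n = x.shape[0]
        n_feat = sd.size
        dx = dy[:, :-1].copy()
        g = dy[:, -1].sum()                       # total grad on the scalar
        # d stat / d x = (x - mean) / (N * n_feat * sd)
        dx += g * (x - mean) / (n * n_feat * sd[None])
        return dx.astype(DTYPE, copy=False)


def fade_in_blend(coarse_upscaled: np.ndarray, fine: np.ndarray,
                  alpha: float) -> np.ndarray:
    """Linear blend (1-alpha)*coarse + alpha*fine used while growing a stage."""
    if coarse_upscaled.shape != fine.shape:
        raise ShapeMismatchError(
            f"fade-in shapes differ: {coarse_upscaled.shape} vs {fine.shape}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    a = DTYPE(alpha)
    return (1 - a) * coarse_upscaled + a * fine


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with per-parameter state; parameters with no gradient are skipped."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.0, beta2: float = 0.99, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._t = [0] * len(self.params)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self._t[i] += 1
            t = self._t[i]
            m, v = self._m[i], self._v[i]
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * np.square(p.grad)
            mhat = m / (1 - self.b1 ** t)
            vhat = v / (1 - self.b2 ** t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)

    def clip_weights(self, limit: float):
        for p in self.params:
            np.clip(p.value, -limit, limit, out=p.value)


def softmax_cross_entropy(logits: np.ndarray,
                          onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-pixel multi-class cross entropy; returns (loss, dlogits)."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n_pix = logits.shape[0] * logits.shape[2] * logits.shape[3]
    loss = float(-(onehot * np.log(p + 1e-12)).sum() / n_pix)
    dlogits = (p - onehot) / n_pix
    return loss, dlogits.astype(DTYPE, copy=False)
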