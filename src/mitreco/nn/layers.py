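"""Layers with explicit forward/backward passes on NHWC float32 arrays.

Convolutions use "same" zero padding (output size ceil(input/stride)) via
an im2col built from kernel-offset slices, which keeps both directions as
plain BLAS matmuls.  Initialisation is either "normal" with a configurable
standard deviation or "scaled" (Glorot-style fan-averaged normal).
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _init_weight(shape, fan_in, fan_out, rng, init, init_std):
    if init == "normal":
        return rng.normal(0.0, init_std, size=shape).astype(DTYPE)
    if init == "scaled":
        std = np.sqrt(2.0 / (fan_in + fan_out))
        return rng.normal(0.0, std, size=shape).astype(DTYPE)
    raise ValueError(f"unknown init {init!r}")


class Layer:
    """Base class; stateless layers leave params/grads empty."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def sublayers(self) -> list["Layer"]:
        return [self]


def _same_pad(n: int, k: int, s: int) -> tuple[int, int, int]:
    out = -(-n // s)
    total = max((out - 1) * s + k - n, 0)
    return out, total // 2, total - total // 2


class Conv2D(Layer):
    def __init__(
        self,
        in_channels: int,
        filters: int,
        kernel: tuple[int, int],
        stride: tuple[int, int] = (1, 1),
        rng: np.random.Generator | None = None,
        init: str = "scaled",
        init_std: float = 1.0,
    ) -> None:
        super().__init__()
        self.kh, self.kw = kernel
        self.sh, self.sw = stride
        self.in_channels = in_channels
        self.filters = filters
        k_in = self.kh * self.kw * in_channels
        rng = rng or np.random.default_rng()
        self.W = _init_weight((k_in, filters), k_in, filters, rng, init, init_std)
        self.b = np.zeros(filters, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, xp, oh, ow):
        n = xp.shape[0]
        cols = np.empty(
            (n, oh, ow, self.kh, self.kw, self.in_channels), dtype=DTYPE
        )
        for i in range(self.kh):
            for j in range(self.kw):
                cols[:, :, :, i, j, :] = xp[
                    :, i : i + self.sh * oh : self.sh, j : j + self.sw * ow : self.sw, :
                ]
        return cols.reshape(n, oh, ow, -1)

    def forward(self, x, training):
        n, h, w, c = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {c}"
            )
        oh, pt, pb = _same_pad(h, self.kh, self.sh)
        ow, pl, pr = _same_pad(w, self.kw, self.sw)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        cols = self._im2col(xp, oh, ow)
        self._cache = (xp.shape, (pt, pl), (h, w), cols)
        return cols @ self.W + self.b

    def backward(self, dy):
        xp_shape, (pt, pl), (h, w), cols = self._cache
        n, oh, ow, f = dy.shape
        dy2 = dy.reshape(-1, f)
        self.grads[0][...] = cols.reshape(-1, cols.shape[-1]).T @ dy2
        self.grads[1][...] = dy2.sum(axis=0)
        dcols = (dy2 @ self.W.T).reshape(
            n, oh, ow, self.kh, self.kw, self.in_channels
        )
        dxp = np.zeros(xp_shape, dtype=DTYPE)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[
                    :, i : i + self.sh * oh : self.sh, j : j + self.sw * ow : self.sw, :
                ] += dcols[:, :, :, i, j, :]
        return dxp[:, pt : pt + h, pl : pl + w, :]


class Dense(Layer):
    def __init__(
        self,
        in_units: int,
        units: int,
        rng: np.random.Generator | None = None,
        init: str = "scaled",
        init_std: float = 1.0,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.W = _init_weight((in_units, units), in_units, units, rng, init, init_std)
        self.b = np.zeros(units, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class ELU(Layer):
    def __init__(self, alpha: float = 1.0) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training):
        y = np.where(x > 0, x, self.alpha * np.expm1(np.minimum(x, 0.0)))
        self._y = y
        return y.astype(DTYPE)

    def backward(self, dy):
        return dy * np.where(self._y > 0, 1.0, self._y + self.alpha).astype(DTYPE)


class Sigmoid(Layer):
    def forward(self, x, training):
        from scipy.special import expit  # overflow-safe logistic

        self._y = expit(x)
        return self._y.astype(DTYPE)

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class HardSigmoid(Layer):
    """clip(0.2 x + 0.5, 0, 1): reaches 0 and 1 exactly, unlike the smooth
    sigmoid, which suits outputs that saturate at the conductivity bounds."""

    def forward(self, x, training):
        self._x = x
        return np.clip(0.2 * x + 0.5, 0.0, 1.0).astype(DTYPE)

    def backward(self, dy):
        inside = (self._x > -2.5) & (self._x < 2.5)
        return dy * 0.2 * inside


class BatchNorm(Layer):
    """Per-channel batch normalisation over (N, H, W) or (N,)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        super().__init__()
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += (1 - self.momentum) * (mean - self.running_mean)
            self.running_var += (1 - self.momentum) * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat.astype(DTYPE), inv.astype(DTYPE), axes, x.shape)
        return (self.gamma * xhat + self.beta).astype(DTYPE)

    def backward(self, dy):
        xhat, inv, axes, shape = self._cache
        m = np.prod([shape[a] for a in axes])
        self.grads[0][...] = (dy * xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        return (
            inv
            / m
            * (m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axes))
        ).astype(DTYPE)


class MaxPool2D(Layer):
    """2x2 max pooling with stride 2 ("valid": trailing odd row/col drop)."""

    def forward(self, x, training):
        n, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        xv = x[:, : oh * 2, : ow * 2, :].reshape(n, oh, 2, ow, 2, c)
        xb = xv.transpose(0, 1, 3, 2, 4, 5).reshape(n, oh, ow, 4, c)
        self._arg = xb.argmax(axis=3)
        self._in_shape = x.shape
        return xb.max(axis=3)

    def backward(self, dy):
        n, oh, ow, c = dy.shape
        db = np.zeros((n, oh, ow, 4, c), dtype=DTYPE)
        np.put_along_axis(db, self._arg[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        db = db.reshape(n, oh, ow, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        dx[:, : oh * 2, : ow * 2, :] = db.reshape(n, oh * 2, ow * 2, c)
        return dx


class AvgPool2D(Layer):
    """2x2 average pooling with stride 2 ("valid")."""

    def forward(self, x, training):
        n, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        self._in_shape = x.shape
        xv = x[:, : oh * 2, : ow * 2, :].reshape(n, oh, 2, ow, 2, c)
        return xv.mean(axis=(2, 4))

    def backward(self, dy):
        n, oh, ow, c = dy.shape
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        spread = np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) / 4.0
        dx[:, : oh * 2, : ow * 2, :] = spread
        return dx


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class _Chain(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def sublayers(self):
        out = []
        for layer in self.layers:
            out.extend(layer.sublayers)
        return out


class ResidualBlock(Layer):
    """Identity-skip block: three conv(3x5) -> ELU -> BN stages, then add.

    Spatial dimensions and channel count are preserved, so the skip is a
    plain addition; the input channel count must equal ``filters``.
    """

    def __init__(
        self,
        in_channels: int,
        filters: int,
        kernel: tuple[int, int] = (3, 5),
        rng: np.random.Generator | None = None,
        init: str = "scaled",
        init_std: float = 1.0,
    ) -> None:
        super().__init__()
        if in_channels != filters:
            raise ValueError(
                f"residual block needs in_channels == filters "
                f"({in_channels} != {filters}); use a bottleneck to change width"
            )
        kw = dict(rng=rng, init=init, init_std=init_std)
        layers: list[Layer] = []
        for _ in range(3):
            layers += [
                Conv2D(filters, filters, kernel, **kw),
                ELU(),
                BatchNorm(filters),
            ]
        self.body = _Chain(layers)

    def forward(self, x, training):
        return x + self.body.forward(x, training)

    def backward(self, dy):
        return dy + self.body.backward(dy)

    @property
    def sublayers(self):
        return self.body.sublayers


class BottleneckBlock(Layer):
    """Width/stride-changing block: first conv strided 1x3, conv 1x1 skip.

    The main path is three conv(3x5) -> ELU -> BN stages with the first
    conv strided 1x3 to compress the position axis; the skip path is a
    1x1 conv with the same 1x3 stride so shapes match at the addition.
    """

    def __init__(
        self,
        in_channels: int,
        filters: int,
        kernel: tuple[int, int] = (3, 5),
        stride: tuple[int, int] = (1, 3),
        rng: np.random.Generator | None = None,
        init: str = "scaled",
        init_std: float = 1.0,
    ) -> None:
        super().__init__()
        kw = dict(rng=rng, init=init, init_std=init_std)
        layers: list[Layer] = [
            Conv2D(in_channels, filters, kernel, stride=stride, **kw),
            ELU(),
            BatchNorm(filters),
        ]
        for _ in range(2):
            layers += [
                Conv2D(filters, filters, kernel, **kw),
                ELU(),
                BatchNorm(filters),
            ]
        self.body = _Chain(layers)
        self.skip = Conv2D(in_channels, filters, (1, 1), stride=stride, **kw)

    def forward(self, x, training):
        return self.skip.forward(x, training) + self.body.forward(x, training)

    def backward(self, dy):
        return self.skip.backward(dy) + self.body.backward(dy)

    @property
    def sublayers(self):
        return self.body.sublayers + [self.skip]
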