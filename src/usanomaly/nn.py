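"""Minimal numpy layer library with manual backpropagation.

The training stack runs on plain numpy (no GPU framework is assumed), so
the handful of layers the convolutional autoencoders need are implemented
here explicitly: strided convolution and transposed convolution via
im2col/col2im, batch normalization, dense layers, LeakyReLU and sigmoid,
plus an Adam optimizer.  Every layer exposes ``forward(x, train)`` and
``backward(dout)``; gradients are verified against numerical
differentiation in the test suite.

Shapes follow the (N, C, H, W) convention throughout.  float64 is used
everywhere: the networks are small, and exact reproducibility across runs
matters more than speed here.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "Dense",
    "LeakyReLU",
    "Sigmoid",
    "Flatten",
    "Reshape",
    "Sequential",
    "Adam",
    "im2col",
    "col2im",
]


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Unfold (N, C, H, W) into (N, C*k*k, L) patch columns."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]  # (N, C, Ho, Wo, k, k)
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols)


def col2im(
    cols: np.ndarray, x_shape: tuple[int, ...], k: int, stride: int, pad: int
) -> np.ndarray:
    """Scatter-add (N, C*k*k, L) patch columns back onto an (N, C, H, W) grid."""
    n, c, h, w = x_shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = cols.reshape(n, c, k, k, ho, wo)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, i, j]
    return xp[:, :, pad : pad + h, pad : pad + w]


class Layer:
    """Base layer; subclasses fill ``params`` / ``grads`` with matching keys."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv2d(Layer):
    """k x k convolution, He-initialised, zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 2,
        pad: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel * kernel
        self.params["W"] = rng.standard_normal(
            (out_channels, in_channels, kernel, kernel)
        ) * np.sqrt(2.0 / fan_in)
        self.params["b"] = np.zeros(out_channels)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.in_channels, self.out_channels = in_channels, out_channels

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cols = im2col(x, k, s, p)
        w2 = self.params["W"].reshape(self.out_channels, -1)
        out = np.matmul(w2, cols) + self.params["b"][:, None]
        self._cache = (x.shape, cols)
        return out.reshape(n, self.out_channels, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache
        n = dout.shape[0]
        k, s, p = self.kernel, self.stride, self.pad
        d2 = dout.reshape(n, self.out_channels, -1)
        w2 = self.params["W"].reshape(self.out_channels, -1)
        self.grads["W"] = np.matmul(d2, cols.transpose(0, 2, 1)).sum(axis=0).reshape(
            self.params["W"].shape
        )
        self.grads["b"] = d2.sum(axis=(0, 2))
        dcols = np.matmul(w2.T, d2)
        return col2im(dcols, x_shape, k, s, p)


class ConvTranspose2d(Layer):
    """Transposed (fractionally-strided) convolution; kernel 4 / stride 2 /
    pad 1 doubles spatial size exactly."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 4,
        stride: int = 2,
        pad: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel * kernel
        self.params["W"] = rng.standard_normal(
            (in_channels, out_channels, kernel, kernel)
        ) * np.sqrt(2.0 / fan_in)
        self.params["b"] = np.zeros(out_channels)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.in_channels, self.out_channels = in_channels, out_channels

    def out_size(self, h: int) -> int:
        return self.stride * (h - 1) + self.kernel - 2 * self.pad

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        ho, wo = self.out_size(h), self.out_size(w)
        w2 = self.params["W"].reshape(self.in_channels, -1)  # (Cin, Cout*k*k)
        cols = np.matmul(w2.T, x.reshape(n, c, h * w))  # (N, Cout*k*k, H*W)
        out = col2im(cols, (n, self.out_channels, ho, wo), k, s, p)
        out += self.params["b"][None, :, None, None]
        self._cache = (x, (ho, wo))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, _ = self._cache
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        dcols = im2col(dout, k, s, p)  # (N, Cout*k*k, H*W)
        w2 = self.params["W"].reshape(self.in_channels, -1)
        dx = np.matmul(w2, dcols).reshape(x.shape)
        self.grads["W"] = np.matmul(x.reshape(n, c, h * w), dcols.transpose(0, 2, 1)).sum(
            axis=0
        ).reshape(self.params["W"].shape)
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        return dx


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        self._cache = (xhat, ivar, x.shape)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][
            None, :, None, None
        ]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivar, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.params["gamma"][None, :, None, None]
        # standard batch-norm backward, reduced over (N, H, W) per channel
        term1 = dxhat
        term2 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        term3 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return ivar[None, :, None, None] * (term1 - term2 - term3)


class Dense(Layer):
    def __init__(
        self, in_features: int, out_features: int, rng: np.random.Generator | None = None
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["W"] = rng.standard_normal((out_features, in_features)) * np.sqrt(
            2.0 / in_features
        )
        self.params["b"] = np.zeros(out_features)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._cache = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grads["W"] = dout.T @ x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._cache = x > 0
        return np.where(self._cache, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._cache, dout, self.slope * dout)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        self._cache = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        y = self._cache
        return dout * y * (1.0 - y)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._cache = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._cache)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]) -> None:
        super().__init__()
        self.shape = shape  # per-sample shape

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._cache = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._cache)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameter_items(self) -> list[tuple[Layer, str]]:
        items: list[tuple[Layer, str]] = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                items.extend(layer.parameter_items())
            else:
                items.extend((layer, name) for name in layer.params)
        return items

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)


class Adam:
    """Adam with conventional (beta1, beta2) = (0.9, 0.999) defaults; the
    learning rate is set externally per step to follow a schedule."""

    def __init__(
        self,
        items: list[tuple[Layer, str]],
        lr: float = 2e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.items = items
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(layer.params[name]) for layer, name in items]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in items]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, (layer, name) in enumerate(self.items):
            g = layer.grads[name]
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
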