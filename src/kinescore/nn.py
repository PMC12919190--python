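"""Minimal 1D neural-network layers with analytic backpropagation.

The ordinal scorer is a small dual-branch network (a 1D CNN over the task
signal plus an MLP over the kinematic features). The layers here provide
exactly what that architecture needs — Conv1d, BatchNorm1d, ReLU,
MaxPool1d, global average pooling, Linear — each with a ``forward`` that
caches what its ``backward`` needs, plus an Adam optimizer. Everything is
plain NumPy; shapes follow the (batch, channels, length) convention.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: parameters in ``params``, matching ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded 1D convolution, stride 1, odd kernel."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel must be odd for same padding")
        self.kernel = kernel
        self.pad = kernel // 2
        scale = np.sqrt(2.0 / (in_ch * kernel))  # He init for ReLU nets
        self.params = {
            "w": rng.normal(0.0, scale, size=(out_ch, in_ch, kernel)),
            "b": np.zeros(out_ch),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        self._xp = xp
        win = sliding_window_view(xp, self.kernel, axis=2)  # (B, C, L, k)
        out = np.einsum("bclk,ock->bol", win, self.params["w"],
                        optimize=True) + self.params["b"][None, :, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        w = self.params["w"]
        xp = self._xp
        L = dout.shape[2]
        win = sliding_window_view(xp, self.kernel, axis=2)
        self.grads["w"] = np.einsum("bclk,bol->ock", win, dout, optimize=True)
        self.grads["b"] = dout.sum(axis=(0, 2))
        dxp = np.zeros_like(xp)
        for j in range(self.kernel):
            dxp[:, :, j:j + L] += np.einsum("oc,bol->bcl", w[:, :, j], dout,
                                            optimize=True)
        return dxp[:, :, self.pad:self.pad + L]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        return (self.params["gamma"][None, :, None] * self._xhat
                + self.params["beta"][None, :, None])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        n = dout.shape[0] * dout.shape[2]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2))
        self.grads["beta"] = dout.sum(axis=(0, 2))
        if not self.training:
            return dout * self.params["gamma"][None, :, None] / std[None, :, None]
        dxhat = dout * self.params["gamma"][None, :, None]
        term = (dxhat - dxhat.mean(axis=(0, 2), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True) / n)
        return term / std[None, :, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling; a trailing odd sample is dropped."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        L2 = L // self.size
        self._in_len = L
        xr = x[:, :, :L2 * self.size].reshape(B, C, L2, self.size)
        self._argmax = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, L2 = dout.shape
        dx = np.zeros((B, C, L2, self.size))
        b, c, l = np.meshgrid(np.arange(B), np.arange(C), np.arange(L2),
                              indexing="ij")
        dx[b, c, l, self._argmax] = dout
        dx = dx.reshape(B, C, L2 * self.size)
        if L2 * self.size < self._in_len:
            dx = np.pad(dx, ((0, 0), (0, 0), (0, self._in_len - L2 * self.size)))
        return dx


class GlobalAvgPool(Layer):
    """(B, C, L) -> (B, C) temporal mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._len = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.repeat(dout[:, :, None], self._len, axis=2) / self._len


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params = {"w": rng.normal(0.0, scale, size=(n_in, n_out)),
                       "b": np.zeros(n_out)}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["w"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["w"].T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def set_training(self, training: bool) -> None:
        for layer in self.layers:
            layer.training = training

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]


class Adam:
    """Adam optimizer over (layer, parameter-name) handles."""

    def __init__(self, handles: list[tuple[object, str]], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.handles = handles
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in handles]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in handles]

    def step(self) -> None:
        self.t += 1
        for i, (layer, name) in enumerate(self.handles):
            g = layer.grads[name]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
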