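"""Minimal 1-D convolutional network in numpy.

A small, fully deterministic CNN (two convolution blocks, global average
pooling, one dense layer, softmax) with hand-written backpropagation and
SGD/Adam/RMSprop optimizers. Sized for calcium-trace classification:
hundreds of time points, a handful of channels, CPU-only training in
seconds to minutes. All randomness flows through a single seeded
generator, so identical seeds give bit-identical parameters and updates
on one thread.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-8


def _windows(x: np.ndarray, k: int) -> np.ndarray:
    """Sliding windows over the last axis: [..., T] -> [..., T-k+1, k]."""
    return np.lib.stride_tricks.sliding_window_view(x, k, axis=-1)


class Conv1d:
    """Same-padded 1-D convolution (cross-correlation), odd kernel only."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        fan_in = in_channels * kernel_size
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_channels, in_channels, kernel_size))
        self.b = np.zeros(out_channels)
        self.k = kernel_size
        self.pad = kernel_size // 2
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:        # x: [B, C, T]
        self._x = x
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        win = _windows(xp, self.k)                          # [B, C, T, K]
        return np.einsum("bctk,fck->bft", win, self.W, optimize=True) \
            + self.b[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:     # dout: [B, F, T]
        xp = np.pad(self._x, ((0, 0), (0, 0), (self.pad, self.pad)))
        win = _windows(xp, self.k)
        self.dW = np.einsum("bctk,bft->fck", win, dout, optimize=True)
        self.db = dout.sum(axis=(0, 2))
        dp = np.pad(dout, ((0, 0), (0, 0), (self.pad, self.pad)))
        dwin = _windows(dp, self.k)                         # [B, F, T, K]
        return np.einsum("bftk,fck->bct", dwin, self.W[:, :, ::-1], optimize=True)

    @property
    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    params = ()


class MaxPool1d:
    """Non-overlapping max pooling; a trailing remainder is dropped."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x):                                   # [B, C, T]
        b, c, t = x.shape
        t2 = (t // self.size) * self.size
        self._in_shape = x.shape
        xr = x[:, :, :t2].reshape(b, c, t2 // self.size, self.size)
        self._arg = xr.argmax(axis=-1)
        return xr.max(axis=-1)

    def backward(self, dout):
        b, c, t = self._in_shape
        t2 = (t // self.size) * self.size
        dx = np.zeros((b, c, t2 // self.size, self.size))
        np.put_along_axis(dx, self._arg[..., None], dout[..., None], axis=-1)
        dx = dx.reshape(b, c, t2)
        if t2 < t:
            dx = np.pad(dx, ((0, 0), (0, 0), (0, t - t2)))
        return dx

    params = ()


class GlobalAvgPool:
    def forward(self, x):                                   # [B, C, T] -> [B, C]
        self._t = x.shape[-1]
        return x.mean(axis=-1)

    def backward(self, dout):                               # [B, C]
        return np.repeat(dout[..., None], self._t, axis=-1) / self._t

    params = ()


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x):                                   # [B, n_in]
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    @property
    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.log(probs[np.arange(y.size), y] + _EPS).mean())


class CNN1d:
    """Two convolution blocks, global average pooling, one dense head."""

    def __init__(self, n_channels: int, n_frames: int, n_filters: int,
                 kernel_size: int, seed: int = 0):
        if kernel_size >= n_frames:
            raise ValueError(
                f"kernel_size {kernel_size} must be smaller than input length {n_frames}"
            )
        rng = np.random.default_rng(seed)
        self.layers = [
            Conv1d(n_channels, n_filters, kernel_size, rng),
            ReLU(),
            MaxPool1d(2),
            Conv1d(n_filters, n_filters, kernel_size, rng),
            ReLU(),
            GlobalAvgPool(),
            Dense(n_filters, 2, rng),
        ]
        self.n_channels = n_channels
        self.n_frames = n_frames

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def parameter_count(self) -> int:
        return sum(arr.size for layer in self.layers
                   for _, arr, _ in (layer.params or ()))

    def get_weights(self) -> list[np.ndarray]:
        return [arr.copy() for layer in self.layers for _, arr, _ in (layer.params or ())]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for name, arr, _ in (layer.params or ()):
                np.copyto(arr, weights[i])
                i += 1


class Optimizer:
    def __init__(self, lr: float):
        self.lr = lr
        self.state: dict[int, dict] = {}

    def step(self, model: CNN1d) -> None:
        for li, layer in enumerate(model.layers):
            for pi, (name, arr, grad_name) in enumerate(layer.params or ()):
                grad = getattr(layer, grad_name)
                self._update((li, pi), arr, grad)

    def _update(self, key, arr, grad):
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, lr: float, momentum: float = 0.9):
        super().__init__(lr)
        self.momentum = momentum

    def _update(self, key, arr, grad):
        v = self.state.setdefault(key, {"v": np.zeros_like(arr)})["v"]
        v *= self.momentum
        v -= self.lr * grad
        arr += v


class RMSprop(Optimizer):
    def __init__(self, lr: float, rho: float = 0.9):
        super().__init__(lr)
        self.rho = rho

    def _update(self, key, arr, grad):
        s = self.state.setdefault(key, {"s": np.zeros_like(arr)})["s"]
        s *= self.rho
        s += (1 - self.rho) * grad * grad
        arr -= self.lr * grad / (np.sqrt(s) + _EPS)


class Adam(Optimizer):
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999):
        super().__init__(lr)
        self.beta1, self.beta2 = beta1, beta2

    def _update(self, key, arr, grad):
        st = self.state.setdefault(
            key, {"m": np.zeros_like(arr), "v": np.zeros_like(arr), "t": 0})
        st["t"] += 1
        st["m"] = self.beta1 * st["m"] + (1 - self.beta1) * grad
        st["v"] = self.beta2 * st["v"] + (1 - self.beta2) * grad * grad
        mhat = st["m"] / (1 - self.beta1 ** st["t"])
        vhat = st["v"] / (1 - self.beta2 ** st["t"])
        arr -= self.lr * mhat / (np.sqrt(vhat) + _EPS)


OPTIMIZERS = {"sgd": SGD, "adam": Adam, "rmsprop": RMSprop}


def make_optimizer(name: str, lr: float) -> Optimizer:
    try:
        return OPTIMIZERS[name](lr)
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}")
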