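"""Minimal numpy layers with manual backpropagation.

Only what the 1D fully-convolutional embedding core needs: same-padded 1D
convolution, per-channel batch normalization, ReLU, inverted dropout, global
average pooling over time, dense layers, row-wise L2 normalization, a fused
softmax/cross-entropy head, and Adam with global gradient-norm clipping.

Data layout is ``(batch, channels, time)`` in float32. Each layer caches the
forward activations it needs and exposes ``params`` / ``grads`` dicts; the
trainer flattens these for the optimizer.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-5


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1dSame(Layer):
    """1D convolution with unit stride and odd-kernel 'same' padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd for symmetric same padding")
        self.k = kernel_size
        self.pad = (kernel_size - 1) // 2
        std = np.sqrt(2.0 / (in_channels * kernel_size))
        self.params["w"] = rng.normal(0.0, std, (out_channels, in_channels, kernel_size)).astype(np.float32)
        self.params["b"] = np.zeros(out_channels, dtype=np.float32)
        self._windows: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, t = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        # im2col: (B, C, T, K) view -> contiguous (B*T, C*K) so the product
        # runs through BLAS instead of a strided einsum loop
        windows = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        cols = np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(b * t, c * self.k)
        w2d = self.params["w"].reshape(self.params["w"].shape[0], c * self.k)
        out = (cols @ w2d.T).reshape(b, t, -1).transpose(0, 2, 1)
        out += self.params["b"][None, :, None]
        if train:
            self._cols = cols
            self._in_shape = x.shape
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, t = self._in_shape
        f = self.params["w"].shape[0]
        dout2d = np.ascontiguousarray(dout.transpose(0, 2, 1)).reshape(b * t, f)
        self.grads["w"] = (dout2d.T @ self._cols).reshape(f, c, self.k)
        self.grads["b"] = dout.sum(axis=(0, 2))
        w2d = self.params["w"].reshape(f, c * self.k)
        dcols = (dout2d @ w2d).reshape(b, t, c, self.k)
        dxp = np.zeros((b, c, t + 2 * self.pad), dtype=np.float32)
        for j in range(self.k):
            dxp[:, :, j : j + t] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, self.pad : self.pad + t]


class BatchNorm1d(Layer):
    """Per-channel normalization over batch and time, with running stats."""

    def __init__(self, n_channels: int, momentum: float = 0.1):
        super().__init__()
        self.params["gamma"] = np.ones(n_channels, dtype=np.float32)
        self.params["beta"] = np.zeros(n_channels, dtype=np.float32)
        self.running_mean = np.zeros(n_channels, dtype=np.float32)
        self.running_var = np.ones(n_channels, dtype=np.float32)
        self.momentum = momentum
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + _EPS)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        if train:
            self._cache = (xhat, inv_std)
        return (self.params["gamma"][None, :, None] * xhat + self.params["beta"][None, :, None]).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = dout.shape[0] * dout.shape[2]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2))
        self.grads["beta"] = dout.sum(axis=(0, 2))
        dxhat = dout * self.params["gamma"][None, :, None]
        sum_dxhat = dxhat.sum(axis=(0, 2), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        dx = (inv_std[None, :, None] / n) * (n * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; the mask generator is supplied per forward pass."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.rate == 0.0:
            return dout
        return dout * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._t = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.repeat(dout[:, :, None], self._t, axis=2) / self._t


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (d_in + d_out))
        self.params["w"] = rng.uniform(-bound, bound, (d_in, d_out)).astype(np.float32)
        self.params["b"] = np.zeros(d_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["w"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["w"].T


class L2Normalize(Layer):
    """Row-wise projection onto the unit hypersphere."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        norm = np.sqrt((x**2).sum(axis=1, keepdims=True))
        norm = np.maximum(norm, 1e-12)
        y = x / norm
        if train:
            self._y, self._norm = y, norm
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        y, norm = self._y, self._norm
        return (dout - y * (dout * y).sum(axis=1, keepdims=True)) / norm


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_with_grad(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.maximum(p[np.arange(n), targets], 1e-12)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, dlogits / n


def clip_global_norm(grads: list[np.ndarray], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most max_norm.

    Returns the post-clip global norm.
    """
    total = float(np.sqrt(sum(float((g**2).sum()) for g in grads)))
    if max_norm > 0 and total > max_norm:
        factor = max_norm / (total + 1e-12)
        for g in grads:
            g *= factor
        return max_norm
    return total


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
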