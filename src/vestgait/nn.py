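"""Minimal numpy neural-network engine.

Implements exactly the layer set the gait classifier needs — 1-D convolution
(stride 1), ReLU, 1-D batch normalization, max pooling, dropout and affine
layers — with hand-written backpropagation, plus the Adam optimizer and a
binary cross-entropy loss computed on logits for numerical stability.
Everything runs in float32; all randomness flows through explicitly passed
``numpy.random.Generator`` objects, so runs are deterministic given a seed.

Layers follow a simple protocol: ``forward(x, mode)`` with mode ``"train"``
(caches stored for the subsequent ``backward``) or ``"eval"`` (deterministic,
running statistics, no caches), and ``params()`` yielding the trainable
:class:`Parameter` objects.
"""

from __future__ import annotations

import numpy as np

from .errors import ContractError


class Parameter:
    """A named trainable tensor with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, mode: str) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class GroupedConv1d(Layer):
    """Independent per-branch 1-D convolutions computed in one stacked call.

    Holds one weight tensor of shape (branches, out_channels, in_channels,
    kernel) with no sharing across branches: the operation is exactly
    ``branches`` separate convolutions (a block-diagonal linear map), batched
    for speed.  Input and output are (N, branches, channels, length).
    """

    def __init__(
        self,
        n_branches: int,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        padding: int,
        rng: np.random.Generator,
        name: str,
    ):
        self.n_branches = n_branches
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = padding
        std = np.sqrt(2.0 / (in_channels * kernel_size))
        self.weight = Parameter(
            f"{name}.weight",
            rng.normal(0.0, std, (n_branches, out_channels, in_channels, kernel_size)),
        )
        self.bias = Parameter(f"{name}.bias", np.zeros((n_branches, out_channels)))

    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, mode: str) -> np.ndarray:
        n, b, c, length = x.shape
        if b != self.n_branches or c != self.in_channels:
            raise ContractError(
                f"{self.weight.name}: expected ({self.n_branches}, "
                f"{self.in_channels}) branch/channel axes, got ({b}, {c})"
            )
        k, p = self.kernel_size, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (p, p)))
        out_len = length + 2 * p - k + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=3)
        # (n,b,c,out,k) -> (b, n*out, c*k)
        cols = np.ascontiguousarray(win.transpose(1, 0, 3, 2, 4)).reshape(
            b, n * out_len, c * k
        )
        wmat = self.weight.value.reshape(b, self.out_channels, c * k)
        y = np.matmul(cols, wmat.transpose(0, 2, 1))  # (b, n*out, c_out)
        y += self.bias.value[:, None, :]
        if mode == "train":
            self._cols = cols
            self._in_len = length
            self._n = n
        return y.reshape(b, n, out_len, self.out_channels).transpose(1, 0, 3, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, b, c_out, out_len = grad.shape
        k, p = self.kernel_size, self.padding
        gmat = np.ascontiguousarray(grad.transpose(1, 0, 3, 2)).reshape(
            b, n * out_len, c_out
        )
        dw = np.matmul(gmat.transpose(0, 2, 1), self._cols)  # (b, c_out, c*k)
        self.weight.grad += dw.reshape(self.weight.value.shape)
        self.bias.grad += gmat.sum(axis=1)
        wmat = self.weight.value.reshape(b, c_out, self.in_channels * k)
        dcols = np.matmul(gmat, wmat)  # (b, n*out, c*k)
        dcols = dcols.reshape(b, n, out_len, self.in_channels, k)
        dxp = np.zeros(
            (n, b, self.in_channels, self._in_len + 2 * p), dtype=np.float32
        )
        for j in range(k):
            dxp[:, :, :, j : j + out_len] += dcols[:, :, :, :, j].transpose(1, 0, 3, 2)
        self._cols = None
        return dxp[:, :, :, p : p + self._in_len] if p else dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray, mode: str) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if mode == "train":
            self._mask = x > 0
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class BatchNorm1d(Layer):
    """Batch normalization over (N,) or (N, L) per feature/channel.

    Training normalizes with biased batch statistics and updates running
    statistics with momentum 0.1; evaluation uses the running statistics,
    making eval outputs independent of batch composition.
    """

    def __init__(self, num_features, name: str, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(f"{name}.gamma", np.ones(num_features))
        self.beta = Parameter(f"{name}.beta", np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self._name = name

    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def buffers(self) -> dict[str, np.ndarray]:
        return {
            f"{self._name}.running_mean": self.running_mean,
            f"{self._name}.running_var": self.running_var,
        }

    def _shape(self, x: np.ndarray):
        if x.ndim == 2:  # (N, F)
            return (0,), (-1,)
        if x.ndim == 3:  # (N, C, L)
            return (0, 2), (-1, 1)
        if x.ndim == 4:  # (N, B, C, L): per (branch, channel) statistics
            return (0, 3), self.running_mean.shape + (1,)
        raise ContractError("BatchNorm1d expects 2-D to 4-D input")

    def forward(self, x: np.ndarray, mode: str) -> np.ndarray:
        axes, bshape = self._shape(x)
        if mode == "train":
            count = x.shape[0] * (x.shape[-1] if x.ndim >= 3 else 1)
            if count < 2:
                raise ContractError("batch normalization needs at least 2 values")
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean.reshape(bshape)) * inv_std.reshape(bshape)
            self._xhat = xhat
            self._inv_std = inv_std
            self._axes = axes
            self._bshape = bshape
            self._count = count
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean.reshape(bshape)) * inv_std.reshape(bshape)
        return self.gamma.value.reshape(bshape) * xhat + self.beta.value.reshape(bshape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes, bshape = self._axes, self._bshape
        xhat = self._xhat
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value.reshape(bshape)
        mean_g = g.mean(axis=axes).reshape(bshape)
        mean_gx = (g * xhat).mean(axis=axes).reshape(bshape)
        dx = (g - mean_g - xhat * mean_gx) * self._inv_std.reshape(bshape)
        self._xhat = None
        return dx.astype(np.float32)


class MaxPool1d(Layer):
    """Max pooling with kernel = stride along the last (time) axis."""

    def __init__(self, pool_size: int = 2):
        self.pool_size = pool_size

    def forward(self, x: np.ndarray, mode: str) -> np.ndarray:
        *lead, length = x.shape
        out_len = length // self.pool_size
        xr = x[..., : out_len * self.pool_size].reshape(
            *lead, out_len, self.pool_size
        )
        if mode == "train":
            self._argmax = xr.argmax(axis=-1)
            self._in_shape = x.shape
        return xr.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        *lead, out_len = grad.shape
        dxr = np.zeros((*lead, out_len, self.pool_size), dtype=np.float32)
        np.put_along_axis(dxr, self._argmax[..., None], grad[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[..., : out_len * self.pool_size] = dxr.reshape(*lead, -1)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in eval mode.  Draws from the given rng."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ContractError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, mode: str) -> np.ndarray:
        if mode != "train" or self.rate == 0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.rate == 0:
            return grad
        return grad * self._mask


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, name: str):
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(
            f"{name}.weight", rng.normal(0.0, std, (out_features, in_features))
        )
        self.bias = Parameter(f"{name}.bias", np.zeros(out_features))

    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, mode: str) -> np.ndarray:
        if mode == "train":
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        dx = grad @ self.weight.value
        self._x = None
        return dx


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - y) / z.size
    return float(loss.mean()), grad.astype(np.float32)


class Adam:
    """Adam with the customary moment coefficients (0.9, 0.999, eps 1e-8)."""

    def __init__(self, params: list[Parameter], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad**2 - v)
            p.value -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def clip_grad_norm(params: list[Parameter], max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``."""
    total = float(np.sqrt(sum(float((p.grad**2).sum()) for p in params)))
    if total > max_norm and total > 0:
        scale = np.float32(max_norm / total)
        for p in params:
            p.grad *= scale
    return total
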