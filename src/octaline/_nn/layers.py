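"""Layers with explicit forward/backward passes on float32 arrays.

Conventions: sequence tensors are (batch, length, channels); flat
tensors are (batch, features).  Each layer caches what its backward
pass needs; `params`/`grads` expose trainable arrays in lock-step
order for the optimizers.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    """Base class; stateless layers only override forward/backward."""

    trainable: bool = False

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_trainable(self) -> int:
        return int(sum(p.size for p in self.params()))


class Conv1D(Layer):
    """1-D convolution along the depth axis, length-preserving padding.

    Weights are stored as (kernel*channels_in, filters); the forward
    pass is one im2col GEMM with a deep reduction axis.  An input
    layer (``input_layer=True``) skips the dX half of its backward
    pass, which no earlier layer would consume.
    """

    trainable = True

    def __init__(self, channels_in: int, filters: int, kernel: int, *,
                 stride: int = 1, input_layer: bool = False,
                 rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        if stride != 1:
            raise ValueError("only stride 1 is supported")
        self.channels_in = channels_in
        self.filters = filters
        self.kernel = kernel
        self.pad = (kernel - 1) // 2
        self.input_layer = input_layer
        fan_in = kernel * channels_in
        self.W = _glorot_uniform(rng, fan_in, filters, (fan_in, filters))
        self.b = np.zeros(filters, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training, rng):
        B, L, C = x.shape
        xp = np.pad(np.asarray(x, dtype=np.float32), ((0, 0), (self.pad, self.pad), (0, 0)))
        # windows: (B, L, C, K) -> (B, L, K, C) -> (B*L, K*C)
        win = sliding_window_view(xp, self.kernel, axis=1)
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B * L, self.kernel * C)
        out = cols @ self.W
        out += self.b
        self._cols = cols
        self._shape = (B, L, C)
        return out.reshape(B, L, self.filters)

    def backward(self, dout):
        B, L, C = self._shape
        d2 = dout.reshape(B * L, self.filters)
        self.dW[...] = self._cols.T @ d2
        self.db[...] = d2.sum(axis=0)
        self._cols = None
        if self.input_layer:
            return None
        dcols = (d2 @ self.W.T).reshape(B, L, self.kernel, C)
        dxp = np.zeros((B, L + 2 * self.pad, C), dtype=np.float32)
        for k in range(self.kernel):
            dxp[:, k:k + L, :] += dcols[:, :, k, :]
        return dxp[:, self.pad:self.pad + L, :]


class MaxPool1D(Layer):
    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x, training, rng):
        B, L, C = x.shape
        if L % self.pool:
            raise ValueError(f"length {L} not divisible by pool {self.pool}")
        self._shape = (B, L, C)
        if self.pool == 2:  # fast pairwise path (ties go to the left member)
            a, b = x[:, ::2, :], x[:, 1::2, :]
            self._left = a >= b
            return np.where(self._left, a, b)
        xr = x.reshape(B, L // self.pool, self.pool, C)
        self._argmax = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, dout):
        B, L, C = self._shape
        if self.pool == 2:
            dx = np.zeros((B, L, C), dtype=np.float32)
            dx[:, ::2, :] = np.where(self._left, dout, 0.0)
            dx[:, 1::2, :] = np.where(self._left, 0.0, dout)
            return dx
        dxr = np.zeros((B, L // self.pool, self.pool, C), dtype=np.float32)
        np.put_along_axis(dxr, self._argmax[:, :, None, :], dout[:, :, None, :], axis=2)
        return dxr.reshape(B, L, C)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape, dtype=np.float32) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    trainable = True

    def __init__(self, units_in: int, units_out: int, *, use_bias: bool = True,
                 rng: np.random.Generator):
        self.use_bias = use_bias
        self.W = _glorot_uniform(rng, units_in, units_out, (units_in, units_out))
        self.dW = np.zeros_like(self.W)
        if use_bias:
            self.b = np.zeros(units_out, dtype=np.float32)
            self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b] if self.use_bias else [self.W]

    def grads(self):
        return [self.dW, self.db] if self.use_bias else [self.dW]

    def forward(self, x, training, rng):
        self._x = x
        out = x @ self.W
        if self.use_bias:
            out += self.b
        return out

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        if self.use_bias:
            self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class BatchNorm(Layer):
    """Feature-wise batch normalization with running statistics."""

    trainable = True

    def __init__(self, features: int, *, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = np.ones(features, dtype=np.float32)
        self.beta = np.zeros(features, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(features, dtype=np.float32)
        self.running_var = np.ones(features, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, training, rng):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        return self.gamma * self._xhat + self.beta

    def backward(self, dout):
        N = dout.shape[0]
        self.dgamma[...] = (dout * self._xhat).sum(axis=0)
        self.dbeta[...] = dout.sum(axis=0)
        dxhat = dout * self.gamma
        # standard batch-norm gradient through the per-batch statistics
        return self._inv_std / N * (
            N * dxhat - dxhat.sum(axis=0) - self._xhat * (dxhat * self._xhat).sum(axis=0)
        )


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Sigmoid(Layer):
    """Numerically stable elementwise sigmoid."""

    def forward(self, x, training, rng):
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)
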