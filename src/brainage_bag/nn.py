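"""Minimal feed-forward neural-network engine on numpy.

Implements exactly the layer set needed by the age predictors: dense layers,
3-D convolutions (kernel 1 or 3, zero-padded "same"), batch normalization,
2x2x2 max pooling, global average pooling, ReLU and dropout, trained with
Adam on a mean-squared-error loss.  Backward passes are hand-written, which
also yields the input-space gradients required by the SmoothGrad saliency
analysis.

Array layout is channels-last: dense inputs are ``(n, features)``, volumes
are ``(n, D, H, W, C)``.  All stochastic operations (weight init, dropout)
draw from explicitly passed numpy Generators, so runs are reproducible.
"""

from __future__ import annotations

import copy

import numpy as np

__all__ = [
    "Dense", "ReLU", "Conv3D", "BatchNorm", "MaxPool3D", "GlobalAvgPool",
    "Dropout", "Flatten", "Sequential", "Adam", "mse_loss",
]


class Layer:
    """Base layer: trainable arrays live in ``params``; matching gradients
    are filled into ``grads`` by :meth:`backward`."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(dtype)
        self.params["b"] = np.zeros(n_out, dtype=dtype)

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gout):
        self.grads["W"] = self._x.T @ gout
        self.grads["b"] = gout.sum(axis=0)
        return gout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gout):
        return gout * self._mask


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Conv3D(Layer):
    """3-D convolution with kernel size 1 or 3 and zero-padded same output."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.k = kernel
        fan_in = c_in * kernel ** 3
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, kernel, c_in, c_out)
        ).astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)

    def _offsets(self):
        k = self.k
        return [(dx, dy, dz) for dx in range(k) for dy in range(k)
                for dz in range(k)]

    def forward(self, x, training, rng):
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0))) if p else x
        n, D, H, W, C = x.shape
        R = n * D * H * W
        Wk = self.params["W"]
        # im2col laid out as (k^3, R, C): each offset slot is a contiguous
        # block copy.  For a single input channel the accumulation collapses
        # to one BLAS gemm on a transposed view (one pass over the output);
        # for wider inputs, k^3 gemms whose outputs stay cache-resident.
        cols = np.empty((k ** 3, R, C), dtype=Wk.dtype)
        for i, (dx, dy, dz) in enumerate(self._offsets()):
            cols[i] = xp[:, dx:dx + D, dy:dy + H, dz:dz + W, :].reshape(R, C)
        self._cols = cols
        self._shape = (n, D, H, W, C)
        if C == 1:
            wmat = Wk.reshape(k ** 3, -1)  # (k^3, F)
            out = cols.reshape(k ** 3, R).T @ wmat + self.params["b"]
        else:
            out = np.empty((R, Wk.shape[-1]), dtype=Wk.dtype)
            out[:] = self.params["b"]
            for i, (dx, dy, dz) in enumerate(self._offsets()):
                out += cols[i] @ Wk[dx, dy, dz]
        return out.reshape(n, D, H, W, -1)

    def backward(self, gout):
        k, p = self.k, self.k // 2
        n, D, H, W, C = self._shape
        c_out = gout.shape[-1]
        gflat = np.ascontiguousarray(gout.reshape(-1, c_out))
        Wk = self.params["W"]
        gW = np.empty_like(Wk)
        gxp = np.zeros((n, D + 2 * p, H + 2 * p, W + 2 * p, C), dtype=Wk.dtype)
        if C == 1:
            R = gflat.shape[0]
            flat_cols = self._cols.reshape(k ** 3, R)
            gW[:] = (flat_cols @ gflat).reshape(k, k, k, 1, c_out)
            gcols = (Wk.reshape(k ** 3, c_out) @ gflat.T)  # (k^3, R)
            for i, (dx, dy, dz) in enumerate(self._offsets()):
                gxp[:, dx:dx + D, dy:dy + H, dz:dz + W, 0] += \
                    gcols[i].reshape(n, D, H, W)
        else:
            for i, (dx, dy, dz) in enumerate(self._offsets()):
                gW[dx, dy, dz] = self._cols[i].T @ gflat
                gxp[:, dx:dx + D, dy:dy + H, dz:dz + W, :] += \
                    (gflat @ Wk[dx, dy, dz].T).reshape(n, D, H, W, C)
        self.grads["W"] = gW
        self.grads["b"] = gflat.sum(axis=0)
        return gxp[:, p:-p, p:-p, p:-p, :] if p else gxp


class BatchNorm(Layer):
    """Per-channel batch normalization over batch and spatial axes, with
    running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x, training, rng):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mu).astype(mu.dtype)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(var.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        self._axes = axes
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, gout):
        axes = self._axes
        xhat = self._xhat
        self.grads["gamma"] = (gout * xhat).sum(axis=axes)
        self.grads["beta"] = gout.sum(axis=axes)
        g = gout * self.params["gamma"] / self._std
        if not self._training:
            return g
        m = xhat.size // xhat.shape[-1]
        return g - g.mean(axis=axes) - xhat * (g * xhat).sum(axis=axes) / m


class MaxPool3D(Layer):
    """2x2x2 max pooling with stride 2; trailing odd slices are dropped.
    Gradient is split evenly among tied maxima within a block."""

    def forward(self, x, training, rng):
        n, D, H, W, C = x.shape
        d, h, w = D // 2, H // 2, W // 2
        if min(d, h, w) < 1:
            raise ValueError(f"spatial size {x.shape[1:4]} too small to pool")
        xc = x[:, : 2 * d, : 2 * h, : 2 * w, :]
        blocks = xc.reshape(n, d, 2, h, 2, w, 2, C)
        out = blocks.max(axis=(2, 4, 6))
        mask = (blocks == out[:, :, None, :, None, :, None, :]).astype(x.dtype)
        self._mask = mask / mask.sum(axis=(2, 4, 6), keepdims=True)
        self._in_shape = x.shape
        return out

    def backward(self, gout):
        n, d, h, w, C = gout.shape
        g = self._mask * gout[:, :, None, :, None, :, None, :]
        g = g.reshape(n, 2 * d, 2 * h, 2 * w, C)
        full = np.zeros(self._in_shape)
        full[:, : 2 * d, : 2 * h, : 2 * w, :] = g
        return full


class GlobalAvgPool(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, gout):
        n, D, H, W, C = self._shape
        g = np.zeros(self._shape, dtype=gout.dtype)
        g += gout[:, None, None, None, :] / (D * H * W)
        return g


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng):
        if training and self.rate > 0.0:
            if rng is None:
                raise ValueError("dropout in training mode needs an rng")
            self._mask = ((rng.random(x.shape) >= self.rate) / (1.0 - self.rate)).astype(x.dtype)
            return x * self._mask
        self._mask = None
        return x

    def backward(self, gout):
        return gout if self._mask is None else gout * self._mask


class Sequential:
    """An ordered layer stack with scalar regression output."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        #: constant added to the raw network output at inference; training on
        #: mean-centered targets keeps the output head near zero, which Adam
        #: handles far better than an offset of tens of years
        self.output_offset = 0.0

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        """Propagate an output-space gradient back to the input; fills every
        layer's parameter gradients and returns the input gradient."""
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Deterministic inference: dropout off, batch-norm running stats."""
        return self.forward(x, training=False).reshape(-1) + self.output_offset

    # -- parameter plumbing -------------------------------------------------

    def parameters(self):
        for layer in self.layers:
            for name, arr in layer.params.items():
                yield layer, name, arr

    def get_state(self) -> list:
        state = [copy.deepcopy(layer.params) for layer in self.layers]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                state.append((layer.running_mean.copy(), layer.running_var.copy()))
        return state

    def set_state(self, state: list) -> None:
        n = len(self.layers)
        for layer, params in zip(self.layers, state[:n]):
            layer.params = copy.deepcopy(params)
        bns = [l for l in self.layers if isinstance(l, BatchNorm)]
        for layer, (rm, rv) in zip(bns, state[n:]):
            layer.running_mean = rm.copy()
            layer.running_var = rv.copy()


class Adam:
    """Adam optimizer over a :class:`Sequential` model's parameters."""

    def __init__(self, model: Sequential, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for layer, name, arr in model.parameters():
            self.m[(id(layer), name)] = np.zeros_like(arr)
            self.v[(id(layer), name)] = np.zeros_like(arr)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, name, arr in self.model.parameters():
            g = layer.grads[name]
            key = (id(layer), name)
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1 ** self.t)
            vhat = self.v[key] / (1 - b2 ** self.t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    pred = pred.reshape(-1)
    diff = pred - target
    return float(np.mean(diff ** 2)), (2.0 * diff / len(diff)).reshape(-1, 1)
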