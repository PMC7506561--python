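"""Minimal NumPy neural-network engine backing the stroke classifiers.

Implements exactly the layer types the two architectures need — valid 2-D
convolution, batch normalisation, inverted dropout, flatten and dense
(applied to the trailing feature axis, so it also serves as the
per-timestep dense of the deep feed-forward net) — with softmax
cross-entropy loss, L2 weight penalties and an Adam optimiser.  Everything
is seeded through a single ``numpy.random.Generator``, so training is
bit-reproducible on a fixed seed.

The convolutions use im2col via ``sliding_window_view`` + ``einsum`` in
both passes, which keeps training on the small frame tensors involved
(≤ a few hundred samples per frame, ≤ 16/32 filters) fast enough on one
CPU core.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def penalty(self) -> float:
        return 0.0


class Conv2D(Layer):
    """Valid (no padding), unit-stride 2-D convolution with fused ReLU.

    Input (N, H, W, C_in) → output (N, H-kh+1, W-kw+1, filters).
    """

    def __init__(self, c_in: int, filters: int, kernel: tuple[int, int],
                 rng: np.random.Generator) -> None:
        super().__init__()
        kh, kw = kernel
        fan_in = kh * kw * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kh, kw, c_in, filters))
        self.b = np.zeros(filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.kernel = kernel

    def forward(self, x, training, rng):
        kh, kw = self.kernel
        # (N, Ho, Wo, C, kh, kw)
        self._cols = sliding_window_view(x, (kh, kw), axis=(1, 2))
        z = np.einsum("nhwcpq,pqcf->nhwf", self._cols, self.W, optimize=True) + self.b
        self._mask = z > 0
        return np.where(self._mask, z, 0.0)

    def backward(self, dout):
        kh, kw = self.kernel
        dz = dout * self._mask
        self.grads[0][...] = np.einsum(
            "nhwcpq,nhwf->pqcf", self._cols, dz, optimize=True
        )
        self.grads[1][...] = dz.sum(axis=(0, 1, 2))
        dz_pad = np.pad(dz, ((0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1), (0, 0)))
        cols = sliding_window_view(dz_pad, (kh, kw), axis=(1, 2))
        W_rot = self.W[::-1, ::-1]
        return np.einsum("nhwfpq,pqcf->nhwc", cols, W_rot, optimize=True)


class BatchNorm(Layer):
    """Per-channel batch normalisation over all leading axes.

    Holds four vectors per channel: learned scale and shift, plus running
    mean and variance used at inference time.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training, rng):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        self._axes = axes
        return self.gamma * self._xhat + self.beta

    def backward(self, dout):
        axes = self._axes
        m = np.prod([dout.shape[a] for a in axes])
        self.grads[0][...] = (dout * self._xhat).sum(axis=axes)
        self.grads[1][...] = dout.sum(axis=axes)
        dxhat = dout * self.gamma
        return self._istd * (
            dxhat
            - dxhat.mean(axis=axes)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes) / m
        )


class Dropout(Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    """Affine map on the trailing axis with optional ReLU and L2 penalties.

    Leading axes are preserved, so on a (N, L, C) tensor this acts as the
    same dense map applied independently at every timestep.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 relu: bool = True, l2_kernel: float = 0.0, l2_bias: float = 0.0) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in) if relu else np.sqrt(1.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.relu = relu
        self.l2_kernel = l2_kernel
        self.l2_bias = l2_bias

    def forward(self, x, training, rng):
        self._x = x
        z = x @ self.W + self.b
        if self.relu:
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        return z

    def backward(self, dout):
        dz = dout * self._mask if self.relu else dout
        x2d = self._x.reshape(-1, self.W.shape[0])
        dz2d = dz.reshape(-1, self.W.shape[1])
        self.grads[0][...] = x2d.T @ dz2d + 2.0 * self.l2_kernel * self.W
        self.grads[1][...] = dz2d.sum(axis=0) + 2.0 * self.l2_bias * self.b
        return dz @ self.W.T

    def penalty(self) -> float:
        return self.l2_kernel * float((self.W**2).sum()) + self.l2_bias * float(
            (self.b**2).sum()
        )


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Network:
    """A layer stack ending in logits; softmax cross-entropy training."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        # Batch-norm running statistics count toward the budget alongside
        # the learned scale/shift (four vectors per channel in total).
        total = sum(p.size for p in self.params)
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                total += layer.running_mean.size + layer.running_var.size
        return total

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None = None) -> np.ndarray:
        rng = rng or np.random.default_rng(0)
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return softmax(x)

    def loss_and_backward(self, x: np.ndarray, y_onehot: np.ndarray,
                          rng: np.random.Generator) -> float:
        probs = self.forward(x, training=True, rng=rng)
        n = x.shape[0]
        eps = 1e-12
        loss = -float((y_onehot * np.log(probs + eps)).sum()) / n
        loss += sum(layer.penalty() for layer in self.layers)
        grad = (probs - y_onehot) / n
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
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


def fit_network(
    net: Network,
    X: np.ndarray,
    y_onehot: np.ndarray,
    *,
    epochs: int,
    batch_size: int,
    learning_rate: float,
    rng: np.random.Generator,
) -> list[float]:
    """Mini-batch Adam training; returns the per-epoch mean loss curve."""
    n = X.shape[0]
    opt = Adam(net.params, lr=learning_rate)
    curve: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            loss = net.loss_and_backward(X[idx], y_onehot[idx], rng)
            opt.step(net.grads)
            losses.append(loss)
        curve.append(float(np.mean(losses)))
    return curve
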