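"""Minimal NumPy neural-network engine for small 1D-convolutional models.

Layers implement analytic forward/backward passes; training uses Adam with
a weighted binary cross-entropy head.  Everything is deterministic given a
seeded ``numpy.random.Generator``.  The engine is intentionally small: the
models built on it have well under 2,000 parameters.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "BatchNorm1d", "Conv1d", "Tanh", "Flatten", "Linear",
    "Sequential", "Adam", "sigmoid", "weighted_bce_with_logits",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def weighted_bce_with_logits(z: np.ndarray, y: np.ndarray, pos_weight: float = 1.0):
    """Mean weighted BCE on logits; returns (loss, dloss/dz).

    Positive examples are weighted by ``pos_weight`` to counter the 1:8
    target/non-target imbalance of the speller paradigm.
    """
    z = z.ravel()
    y = y.ravel().astype(float)
    w = np.where(y == 1.0, pos_weight, 1.0)
    # log(1 + e^-|z|) is stable for both signs
    log1p = np.log1p(np.exp(-np.abs(z)))
    loss_i = w * (np.maximum(z, 0) - z * y + log1p)
    p = sigmoid(z)
    grad = w * (p - y) / len(z)
    return float(loss_i.mean()), grad


class Layer:
    """Base layer: forward caches what backward needs; params/grads exposed."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[np.ndarray]:
        return []

    def gradients(self) -> list[np.ndarray]:
        return []


class BatchNorm1d(Layer):
    """Per-channel normalization over (batch, length), as in torch's BatchNorm1d.

    Batch statistics during training, exponential running averages at
    inference (momentum 0.1).
    """

    def __init__(self, n_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(n_channels)
        self.beta = np.zeros(n_channels)
        self.dgamma = np.zeros(n_channels)
        self.dbeta = np.zeros(n_channels)
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)

    def forward(self, x, train):
        # x: (B, C, L)
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) * self._istd[None, :, None]
        self._train = train
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, grad):
        xhat, istd = self._xhat, self._istd
        self.dgamma = (grad * xhat).sum(axis=(0, 2))
        self.dbeta = grad.sum(axis=(0, 2))
        if not self._train:
            return grad * (self.gamma * istd)[None, :, None]
        m = grad.shape[0] * grad.shape[2]
        g = grad * self.gamma[None, :, None]
        term = (
            g
            - g.mean(axis=(0, 2))[None, :, None]
            - xhat * (g * xhat).mean(axis=(0, 2))[None, :, None]
        )
        return term * istd[None, :, None]

    def parameters(self):
        return [self.gamma, self.beta]

    def gradients(self):
        return [self.dgamma, self.dbeta]


class Conv1d(Layer):
    """1D convolution (cross-correlation) with stride, zero padding and groups.

    ``groups = in_channels`` with ``out_channels = in_channels`` is a
    depthwise convolution (one kernel per channel); ``kernel = 1`` is a
    pointwise convolution.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 rng: np.random.Generator | None = None):
        if in_channels % groups or out_channels % groups:
            raise ValueError("groups must divide both channel counts")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self.groups = groups
        fan_in = (in_channels // groups) * kernel
        bound = 1.0 / np.sqrt(fan_in)
        rng = rng or np.random.default_rng(0)
        self.weight = rng.uniform(-bound, bound, (out_channels, in_channels // groups, kernel))
        self.bias = rng.uniform(-bound, bound, out_channels)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)

    def out_len(self, in_len: int) -> int:
        span = in_len + 2 * self.padding - self.kernel
        if span < 0:
            raise ValueError(
                f"kernel {self.kernel} larger than padded input {in_len + 2 * self.padding}"
            )
        return span // self.stride + 1

    def forward(self, x, train):
        B, C, L = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {C}")
        Lo = self.out_len(L)
        xp = np.pad(x, ((0, 0), (0, 0), (self.padding, self.padding)))
        # windows: (B, C, Lo, k)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        win = win[:, :, :: self.stride, :][:, :, :Lo, :]
        self._win = win
        self._in_shape = x.shape
        G = self.groups
        if G == 1:
            out = np.einsum("oct,bclt->bol", self.weight, win, optimize=True)
        else:
            cg = self.in_channels // G
            og = self.out_channels // G
            wg = self.weight.reshape(G, og, cg, self.kernel)
            xg = win.reshape(B, G, cg, Lo, self.kernel)
            out = np.einsum("goct,bgclt->bgol", wg, xg, optimize=True)
            out = out.reshape(B, self.out_channels, Lo)
        return out + self.bias[None, :, None]

    def backward(self, grad):
        B, C, L = self._in_shape
        win = self._win
        Lo = grad.shape[2]
        G = self.groups
        self.dbias = grad.sum(axis=(0, 2))
        if G == 1:
            self.dweight = np.einsum("bol,bclt->oct", grad, win, optimize=True)
            dwin = np.einsum("bol,oct->bclt", grad, self.weight, optimize=True)
        else:
            cg = self.in_channels // G
            og = self.out_channels // G
            gg = grad.reshape(B, G, og, Lo)
            xg = win.reshape(B, G, cg, Lo, self.kernel)
            wg = self.weight.reshape(G, og, cg, self.kernel)
            dw = np.einsum("bgol,bgclt->goct", gg, xg, optimize=True)
            self.dweight = dw.reshape(self.out_channels, cg, self.kernel)
            dwin = np.einsum("bgol,goct->bgclt", gg, wg, optimize=True)
            dwin = dwin.reshape(B, C, Lo, self.kernel)
        dxp = np.zeros((B, C, L + 2 * self.padding))
        for t in range(self.kernel):
            sl = slice(t, t + Lo * self.stride, self.stride)
            dxp[:, :, sl] += dwin[:, :, :, t]
        p = self.padding
        return dxp[:, :, p:p + L] if p else dxp

    def parameters(self):
        return [self.weight, self.bias]

    def gradients(self):
        return [self.dweight, self.dbias]


class Tanh(Layer):
    def forward(self, x, train):
        self._out = np.tanh(x)
        return self._out

    def backward(self, grad):
        return grad * (1.0 - self._out**2)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        bound = 1.0 / np.sqrt(in_features)
        rng = rng or np.random.default_rng(0)
        self.weight = rng.uniform(-bound, bound, (out_features, in_features))
        self.bias = rng.uniform(-bound, bound, out_features)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)

    def forward(self, x, train):
        self._x = x
        return x @ self.weight.T + self.bias

    def backward(self, grad):
        self.dweight = grad.T @ self._x
        self.dbias = grad.sum(axis=0)
        return grad @ self.weight

    def parameters(self):
        return [self.weight, self.bias]

    def gradients(self):
        return [self.dweight, self.dbias]


class Sequential:
    """Ordered layer stack ending in a logit; the sigmoid lives in the loss."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.parameters()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.gradients()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state(self) -> list[np.ndarray]:
        arrs = [p.copy() for p in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                arrs += [layer.running_mean.copy(), layer.running_var.copy()]
        return arrs

    def load_state(self, arrs: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, a in zip(params, arrs[: len(params)]):
            p[...] = a
        rest = arrs[len(params):]
        i = 0
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = rest[i].copy()
                layer.running_var = rest[i + 1].copy()
                i += 2


class Adam:
    def __init__(self, model: Sequential, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in model.parameters()]
        self.v = [np.zeros_like(p) for p in model.parameters()]

    def step(self) -> None:
        self.t += 1
        for p, g, m, v in zip(self.model.parameters(), self.model.gradients(),
                              self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
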