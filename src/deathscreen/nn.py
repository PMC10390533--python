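"""Minimal numpy neural-network engine.

Self-contained layers (conv, batch-norm, linear), an Adam optimizer and the
L2-normalisation used ahead of the contrastive loss. Forward passes cache
what their analytic backward passes need; gradients are verified against
finite differences in the test suite. Convolution is im2col + BLAS matmul,
which is fast enough to train the small test backbone on a single CPU.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """3x3-style convolution with zero padding, stride, He initialisation."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        padding: int = 1,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = in_channels * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, k, k))
        self.weight = Param(w.astype(dtype), "conv.weight")
        self.bias = Param(np.zeros(out_channels, dtype=dtype), "conv.bias")
        self.stride = stride
        self.padding = padding
        self.kernel_size = k
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.weight.value.shape[1]:
            raise ValueError(
                f"expected {self.weight.value.shape[1]} input channels, got {c}"
            )
        k, s, p = self.kernel_size, self.stride, self.padding
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (N, C, OH, OW, k, k)
        cols = np.ascontiguousarray(
            win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c, k * k)
        )
        # accumulate channel by channel in fixed order: an input channel that
        # is identically zero then contributes exact zeros, so a kernel
        # extended with adapt_first_layer reproduces the narrower convolution
        # bit-for-bit on inputs whose extra channel is zero
        wmat = self.weight.value.reshape(self.weight.value.shape[0], c, k * k)
        out = np.broadcast_to(self.bias.value, (n * oh * ow, wmat.shape[0])).copy()
        for ci in range(c):
            out += cols[:, ci] @ wmat[:, ci].T
        out = out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)
        if train:
            self._cache = (cols, (n, c, h, w), (oh, ow))
        return np.ascontiguousarray(out)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        assert self._cache is not None, "backward before forward(train=True)"
        cols, (n, c, h, w), (oh, ow) = self._cache
        k, s, p = self.kernel_size, self.stride, self.padding
        cout = self.weight.value.shape[0]
        g2 = gout.transpose(0, 2, 3, 1).reshape(-1, cout)
        self.weight.grad += (
            g2.T @ cols.reshape(n * oh * ow, c * k * k)
        ).reshape(self.weight.value.shape)
        self.bias.grad += g2.sum(axis=0)
        wmat = self.weight.value.reshape(cout, -1)
        dcols = (g2 @ wmat).reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=gout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += dcols[..., i, j]
        self._cache = None
        return dxp[:, :, p:p + h, p:p + w]


class BatchNorm2d(Layer):
    """Channel-wise batch normalisation with a hard freeze switch.

    Frozen (the default in training here): running statistics are used in
    every forward pass and never updated, and gamma/beta are excluded from
    the trainable parameters — the forward output for a sample is then
    independent of the rest of the batch.
    """

    def __init__(
        self, channels: int, frozen: bool = True, momentum: float = 0.1,
        eps: float = 1e-5, dtype=np.float32,
    ) -> None:
        self.gamma = Param(np.ones(channels, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.frozen = frozen
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [] if self.frozen else [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        g = self.gamma.value[None, :, None, None]
        b = self.beta.value[None, :, None, None]
        if self.frozen or not train:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            out = g * (x - self.running_mean[None, :, None, None]) * inv[None, :, None, None] + b
            if train:
                self._cache = ("frozen", inv)
            return out
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
        self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        self._cache = ("train", xhat, inv)
        return g * xhat + b

    def backward(self, gout: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        mode = self._cache[0]
        g = self.gamma.value[None, :, None, None]
        if mode == "frozen":
            inv = self._cache[1]
            self._cache = None
            return gout * g * inv[None, :, None, None]
        _, xhat, inv = self._cache
        self._cache = None
        m = gout.shape[0] * gout.shape[2] * gout.shape[3]
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gout.sum(axis=(0, 2, 3))
        dxhat = gout * g
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        out = gout * self._mask
        self._mask = None
        return out


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def __init__(self) -> None:
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        assert self._shape is not None
        n, c, h, w = self._shape
        self._shape = None
        return np.broadcast_to(gout[:, :, None, None], (n, c, h, w)).copy() / (h * w)


class Linear(Layer):
    def __init__(
        self, in_features: int, out_features: int,
        rng: np.random.Generator | None = None, dtype=np.float32,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features))
        self.weight = Param(w.astype(dtype), "linear.weight")
        self.bias = Param(np.zeros(out_features, dtype=dtype), "linear.bias")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.weight.value.shape[1]:
            raise ValueError(
                f"expected {self.weight.value.shape[1]} features, got {x.shape[1]}"
            )
        if train:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.weight.grad += gout.T @ self._x
        self.bias.grad += gout.sum(axis=0)
        x = self._x
        self._x = None
        return gout @ self.weight.value


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout


def l2_normalize(u: np.ndarray, eps: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise unit-normalise; returns (z, norms) for use in backward."""
    norms = np.sqrt((u * u).sum(axis=1, keepdims=True))
    norms = np.maximum(norms, eps)
    return u / norms, norms


def l2_normalize_backward(
    u: np.ndarray, z: np.ndarray, norms: np.ndarray, gz: np.ndarray
) -> np.ndarray:
    """Backward of row-wise L2 normalisation z = u / ||u||."""
    dot = (gz * z).sum(axis=1, keepdims=True)
    return (gz - dot * z) / norms


class Adam:
    """Standard Adam with bias correction."""

    def __init__(
        self, params: list[Param], lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class SGD:
    def __init__(self, params: list[Param], lr: float = 1e-2) -> None:
        self.params = params
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            p.value -= self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
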