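"""Layers and optimizer for the NumPy autodiff engine.

Layers hold their parameters as `Tensor`s with `requires_grad=True` and
expose `__call__(x, train)` plus `parameters()` / `state()` for
checkpointing.  Initialization follows He (conv / leaky-ReLU fan-in) with an
explicitly seeded generator so models are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, conv_transpose2d

DTYPE = np.float32


class Module:
    """Base class: recursive parameter / buffer collection."""

    def parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, attr in vars(self).items():
            if isinstance(attr, Tensor) and attr.requires_grad:
                params[name] = attr
            elif isinstance(attr, Module):
                for k, v in attr.parameters().items():
                    params[f"{name}.{k}"] = v
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        for k, v in item.parameters().items():
                            params[f"{name}.{i}.{k}"] = v
        return params

    def buffers(self) -> dict[str, np.ndarray]:
        bufs: dict[str, np.ndarray] = {}
        for name, attr in vars(self).items():
            if isinstance(attr, Module):
                for k, v in attr.buffers().items():
                    bufs[f"{name}.{k}"] = v
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        for k, v in item.buffers().items():
                            bufs[f"{name}.{i}.{k}"] = v
        if isinstance(self, BatchNorm2d):
            bufs["running_mean"] = self.running_mean
            bufs["running_var"] = self.running_var
        return bufs

    def load_buffers(self, bufs: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, attr in vars(self).items():
            if isinstance(attr, Module):
                attr.load_buffers(bufs, f"{prefix}{name}.")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        item.load_buffers(bufs, f"{prefix}{name}.{i}.")
        if isinstance(self, BatchNorm2d):
            self.running_mean = bufs[f"{prefix}running_mean"].copy()
            self.running_var = bufs[f"{prefix}running_var"].copy()


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(DTYPE), requires_grad=True)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 padding: int, rng: np.random.Generator):
        self.stride = stride
        self.padding = padding
        self.weight = _he_init(rng, (c_out, c_in, kernel, kernel), c_in * kernel * kernel)
        self.bias = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    """Stride-2 transposed convolution that exactly doubles H and W."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.weight = _he_init(rng, (c_in, c_out, kernel, kernel), c_in * kernel * kernel)
        self.bias = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        _, _, H, W = x.shape
        p = (self.kernel - 1) // 2
        return conv_transpose2d(x, self.weight, self.bias, stride=2,
                                padding=p, out_hw=(2 * H, 2 * W))


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel, with running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        if train:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(-1)).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1)).astype(DTYPE)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = _he_init(rng, (n_in, n_out), n_in)
        self.bias = Tensor(np.zeros(n_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return x @ self.weight + self.bias


class Adam:
    """Adaptive-moment optimizer (Kingma & Ba defaults except the lr)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bias1
            vhat = self.v[k] / bias2
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype
            )
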