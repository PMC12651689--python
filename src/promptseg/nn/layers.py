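"""Neural-network building blocks on top of the autodiff engine.

Only what the segmentation architecture needs: Linear, Conv2d (stride 1),
ConvTranspose2x2 (stride 2), BatchNorm2d with running statistics, and
Dropout.  Parameters are initialised from an explicit
`numpy.random.Generator` so every model build is reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Parameter", "Linear", "Conv2d", "ConvTranspose2x2",
           "BatchNorm2d", "Dropout"]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module system: parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for obj in self.__dict__.values():
            for p in _collect(obj):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for obj in self.__dict__.values():
            mods.extend(_collect_modules(obj))
        return mods

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # state is a flat list of arrays in discovery order (incl. BN buffers)
    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]):
        params = self.parameters()
        bn = [m for m in self.modules() if isinstance(m, BatchNorm2d)]
        expected = len(params) + 2 * len(bn)
        if len(arrays) != expected:
            raise ValueError(f"state mismatch: got {len(arrays)}, expected {expected}")
        for p, a in zip(params, arrays[:len(params)]):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=p.data.dtype).copy()
        rest = arrays[len(params):]
        for i, m in enumerate(bn):
            m.running_mean = np.asarray(rest[2 * i], dtype=np.float64).copy()
            m.running_var = np.asarray(rest[2 * i + 1], dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(obj):
    if isinstance(obj, Parameter):
        yield obj
    elif isinstance(obj, Module):
        yield from obj.parameters()
    elif isinstance(obj, (list, tuple)):
        for item in obj:
            yield from _collect(item)
    elif isinstance(obj, dict):
        for item in obj.values():
            yield from _collect(item)


def _collect_modules(obj):
    if isinstance(obj, Module):
        yield from obj.modules()
    elif isinstance(obj, (list, tuple)):
        for item in obj:
            yield from _collect_modules(item)
    elif isinstance(obj, dict):
        for item in obj.values():
            yield from _collect_modules(item)


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, zero_init: bool = False,
                 bias_init: float = 0.0):
        super().__init__()
        if zero_init:
            w = np.zeros((in_features, out_features))
        else:
            w = _he_normal(rng, (in_features, out_features), in_features)
        self.weight = Parameter(w)
        self.bias = Parameter(np.full(out_features, float(bias_init)))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """3x3 (or any odd k) stride-1 convolution with same-size padding by default."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int | None = None):
        super().__init__()
        k = kernel_size
        self.padding = (k - 1) // 2 if padding is None else padding
        fan_in = in_channels * k * k
        self.weight = Parameter(_he_normal(rng, (out_channels, in_channels, k, k), fan_in))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, padding=self.padding)


class ConvTranspose2x2(Module):
    """2x2-kernel stride-2 transposed convolution: doubles spatial resolution."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_he_normal(
            rng, (in_channels, out_channels, 2, 2), in_channels * 4))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2x2(self.weight, self.bias)


class BatchNorm2d(Module):
    """Batch normalization over (N,H,W) per channel, eps 1e-5, momentum 0.1.

    Training uses batch statistics and updates running estimates; eval uses
    the running estimates.  Batch size 1 is permitted in training but the
    batch variance is then poorly estimated — documented instability.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var = (1 - m) * self.running_var + m * unbiased
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
            xhat = (x - mu) / sd
        c = x.shape[1]
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  Masks are drawn from the
    generator handed to `forward` so training stays seed-reproducible."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("Dropout in training mode needs an rng")
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep) / keep
        return x * mask
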