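"""Layer abstractions over the autodiff core: parameter containers with
seeded initialization, train/eval switching, and state serialization."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import core
from .core import Tensor

DEFAULT_DTYPE = np.float32


class Parameter(Tensor):
    """A tensor that is part of a module's learnable state."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class: automatic registration of parameters and submodules."""

    def __init__(self):
        object.__setattr__(self, "_parameters", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._parameters.items():
            yield (f"{prefix}{name}", p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- mode ------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- serialization ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                state[f"{name}.running_mean"] = m.running_mean.copy()
                state[f"{name}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            if name not in state:
                raise KeyError(f"missing parameter in state dict: {name}")
            if state[name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=p.data.dtype).copy()
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"{name}.running_mean"],
                                            dtype=m.running_mean.dtype).copy()
                m.running_var = np.asarray(state[f"{name}.running_var"],
                                           dtype=m.running_var.dtype).copy()

    def _named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield (prefix.rstrip("."), self)
        for name, m in self._modules.items():
            yield from m._named_modules(prefix=f"{prefix}{name}.")

    def freeze_bn(self) -> "Module":
        """Make every batch-norm layer use its running statistics even in
        train mode (used for train/eval consistency checks and fine control)."""
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                m.frozen = True
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)
        self._layers = layers

    def forward(self, x: Tensor) -> Tensor:
        for layer in self._layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """Stride-1 2-D convolution with 'same' zero padding by default."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int | None = None,
                 dilation: int = 1, bias: bool = True, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        self.padding = dilation * (kernel_size - 1) // 2 if padding is None else padding
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std,
                                           (out_channels, in_channels,
                                            kernel_size, kernel_size)).astype(dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}")
        return core.conv2d(x, self.weight, self.bias,
                           pad=self.padding, dilation=self.dilation)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator,
                 padding: int | None = None, bias: bool = True, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.channels = channels
        self.padding = (kernel_size - 1) // 2 if padding is None else padding
        std = np.sqrt(2.0 / (kernel_size * kernel_size))
        self.weight = Parameter(rng.normal(0.0, std,
                                           (channels, kernel_size, kernel_size)).astype(dtype))
        self.bias = Parameter(np.zeros(channels, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} input channels, got {x.shape[1]}")
        return core.depthwise_conv2d(x, self.weight, self.bias, pad=self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running inference statistics.

    Running variance is updated with the biased batch estimate so that frozen
    statistics reproduce the training-mode normalization exactly.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=DEFAULT_DTYPE):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.frozen = False
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        use_batch = self.training and not self.frozen
        out, mu, v = core.batch_norm2d(x, self.gamma, self.beta,
                                       self.running_mean, self.running_var,
                                       self.eps, use_batch)
        if use_batch:
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(
                self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * v).astype(
                self.running_var.dtype)
        return out


class LayerNorm(Module):
    def __init__(self, channels: int, eps: float = 1e-5, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return core.layer_norm(x, self.gamma, self.beta, self.eps)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True, dtype=DEFAULT_DTYPE):
        super().__init__()
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, std, (in_features, out_features)).astype(dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = core.matmul(x, self.weight)
        if self.bias is not None:
            out = core.add(out, self.bias)
        return out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return core.relu(x)


class ConvBNReLU(Module):
    """conv -> batch norm -> ReLU, the network's standard unit."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dilation: int = 1, bias: bool = False,
                 dtype=DEFAULT_DTYPE):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size, rng,
                           dilation=dilation, bias=bias, dtype=dtype)
        self.bn = BatchNorm2d(out_channels, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return core.relu(self.bn(self.conv(x)))


class DWSeparableConvBNReLU(Module):
    """Depthwise 3x3 filter followed by a pointwise 1x1 mix, then BN + ReLU.

    The parameter-frugal workhorse of the lightweight encoder-decoder.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, kernel_size: int = 3,
                 bias: bool = False, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.depthwise = DepthwiseConv2d(in_channels, kernel_size, rng,
                                         bias=False, dtype=dtype)
        self.pointwise = Conv2d(in_channels, out_channels, 1, rng,
                                bias=bias, dtype=dtype)
        self.bn = BatchNorm2d(out_channels, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return core.relu(self.bn(self.pointwise(self.depthwise(x))))
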