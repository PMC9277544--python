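"""The three context modules of the segmentation network.

* :class:`ECCBlock` — enhanced context-calibrated convolution: a
  split-fuse-select unit that gates one channel half with a sigmoid attention
  map built from a downsample/convolve/upsample calibration path.
* :class:`PCFBlock` — progressive context-aware fusion: a local 3x3 branch, a
  dilated "surrounding" branch, and a softmax global-attention-pooled context
  vector passed through a channel bottleneck.
* :class:`MPABlock` — multi-scale pyramid aggregation: five decoder levels
  upsampled to a common resolution, concatenated, projected, and re-weighted
  by squeeze-and-excitation.

Each block preserves its contract shape and is a pure function of its input
and parameters; learnable weights are drawn from a caller-supplied seeded
generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor, core
from .nn.modules import DEFAULT_DTYPE

__all__ = [
    "ECCConfig", "PCFConfig", "MPAConfig",
    "ECCBlock", "PCFBlock", "MPABlock",
    "ecc_forward", "context_calibrate", "pcf_forward", "mpa_forward",
    "se_reweight",
]


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class ECCConfig:
    """Configuration of the enhanced context-calibrated block.

    calibration_rate is the spatial down/up factor of the calibration path;
    use_depthwise selects depthwise-separable 3x3 units for the inner
    transforms (the lightweight default).
    """

    in_channels: int
    calibration_rate: int = 4
    use_depthwise: bool = True

    def __post_init__(self):
        if self.in_channels < 2 or self.in_channels % 2:
            raise ValueError(f"in_channels must be even and >= 2, got {self.in_channels}")
        if self.calibration_rate < 2 or not _is_power_of_two(self.calibration_rate):
            raise ValueError(
                f"calibration_rate must be a power of two >= 2, got {self.calibration_rate}")


@dataclass(frozen=True)
class PCFConfig:
    """Configuration of the progressive context-aware fusion block."""

    in_channels: int
    dilation: int = 5
    bottleneck_ratio: int = 4

    def __post_init__(self):
        if self.in_channels < 2 or self.in_channels % 2:
            raise ValueError(f"in_channels must be even and >= 2, got {self.in_channels}")
        if self.dilation < 1:
            raise ValueError(f"dilation must be positive, got {self.dilation}")
        if self.bottleneck_ratio < 1 or self.in_channels % self.bottleneck_ratio:
            raise ValueError(
                f"bottleneck_ratio must divide in_channels "
                f"({self.in_channels} % {self.bottleneck_ratio} != 0)")


@dataclass(frozen=True)
class MPAConfig:
    """Configuration of the multi-scale pyramid aggregation head."""

    level_channels: tuple[int, ...] = (16, 32, 64, 128, 160)
    fused_channels: int = 32
    se_ratio: int = 4

    def __post_init__(self):
        object.__setattr__(self, "level_channels", tuple(self.level_channels))
        if len(self.level_channels) != 5:
            raise ValueError(
                f"exactly 5 pyramid levels required, got {len(self.level_channels)}")
        if any(c < 1 for c in self.level_channels):
            raise ValueError("level_channels must be positive")
        if self.fused_channels % self.se_ratio:
            raise ValueError(
                f"fused_channels ({self.fused_channels}) must be divisible by "
                f"se_ratio ({self.se_ratio})")


def _f_hat(channels_in: int, channels_out: int, rng, use_depthwise: bool,
           bias: bool, dtype) -> nn.Module:
    """The 3x3 conv -> BN -> ReLU transform used throughout the ECC block."""
    if use_depthwise:
        return nn.DWSeparableConvBNReLU(channels_in, channels_out, rng,
                                        bias=bias, dtype=dtype)
    return nn.ConvBNReLU(channels_in, channels_out, 3, rng, bias=bias, dtype=dtype)


class ECCBlock(nn.Module):
    """Enhanced context-calibrated convolution (split-fuse-select).

    The input is split by a learned 1x1 projection into two C/2 halves: an
    identity-preserving branch (1x1 conv + BN + ReLU) and a calibrated branch
    whose features are gated by a sigmoid attention map computed from a
    pooled-and-refiltered copy of the same half, developing long-range spatial
    dependence at low cost. The output adds the block input residually.
    """

    def __init__(self, config: ECCConfig, rng: np.random.Generator,
                 bias: bool = False, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.config = config
        c, half = config.in_channels, config.in_channels // 2
        self.split = nn.Conv2d(c, c, 1, rng, bias=bias, dtype=dtype)
        self.identity_branch = nn.ConvBNReLU(half, half, 1, rng, bias=bias, dtype=dtype)
        self.feature = _f_hat(half, half, rng, config.use_depthwise, bias, dtype)
        self.calibration = _f_hat(half, half, rng, config.use_depthwise, bias, dtype)
        self.fuse = _f_hat(half, half, rng, config.use_depthwise, bias, dtype)

    def _check_spatial(self, x: Tensor) -> None:
        r = self.config.calibration_rate
        n, c, h, w = x.shape
        if c != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} channels, got {c}")
        for name, dim in (("height", h), ("width", w)):
            if dim % r:
                raise ValueError(
                    f"{name} ({dim}) must be divisible by calibration_rate {r}")

    def calibrate(self, x2: Tensor) -> Tensor:
        """Attention map sigma(X2 + Up(F(Down(X2)))), entries strictly in (0, 1)."""
        r = self.config.calibration_rate
        n, c, h, w = x2.shape
        if c != self.config.in_channels // 2:
            raise ValueError(
                f"calibration path expects {self.config.in_channels // 2} channels, got {c}")
        for name, dim in (("height", h), ("width", w)):
            if dim % r:
                raise ValueError(
                    f"{name} ({dim}) must be divisible by calibration_rate {r}")
        down = core.avg_pool2d(x2, r)
        up = core.bilinear_resize(self.calibration(down), h, w)
        return core.sigmoid(x2 + up)

    def forward(self, x: Tensor) -> Tensor:
        x = nn.as_tensor(x)
        self._check_spatial(x)
        half = self.config.in_channels // 2
        s = self.split(x)
        x1 = core.narrow(s, 1, 0, half)
        x2 = core.narrow(s, 1, half, half)
        x1p = self.identity_branch(x1)
        x2p = self.feature(x2)
        att = self.calibrate(x2)
        fused = self.fuse(att * x2p)
        return x + core.concat([x1p, fused], axis=1)


class PCFBlock(nn.Module):
    """Progressive context-aware fusion at the encoder bottleneck.

    A 1x1 compression to C/2 feeds a local 3x3 extractor and a dilated
    (default rate 5) surrounding extractor; their concatenation x' is pooled
    by softmax attention over all spatial positions into a global context
    vector, transformed by a layer-normalized channel bottleneck, and
    broadcast back onto x'. The block input is added residually.
    """

    def __init__(self, config: PCFConfig, rng: np.random.Generator,
                 bias: bool = False, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.config = config
        c, half = config.in_channels, config.in_channels // 2
        hidden = c // config.bottleneck_ratio
        self.compress = nn.ConvBNReLU(c, half, 1, rng, bias=bias, dtype=dtype)
        self.local = nn.ConvBNReLU(half, half, 3, rng, bias=bias, dtype=dtype)
        self.surround = nn.ConvBNReLU(half, half, 3, rng,
                                      dilation=config.dilation, bias=bias, dtype=dtype)
        self.attn_logit = nn.Conv2d(c, 1, 1, rng, bias=True, dtype=dtype)
        self.s2 = nn.Linear(c, hidden, rng, dtype=dtype)
        self.ln = nn.LayerNorm(hidden, dtype=dtype)
        self.s3 = nn.Linear(hidden, c, rng, dtype=dtype)

    def _branches(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} channels, got {x.shape[1]}")
        compressed = self.compress(x)
        return core.concat([self.local(compressed), self.surround(compressed)], axis=1)

    def _beta(self, xprime: Tensor) -> Tensor:
        n, _, h, w = xprime.shape
        logits = self.attn_logit(xprime)
        flat = core.reshape(logits, (n, 1, h * w))
        return core.reshape(core.softmax(flat, axis=-1), (n, 1, h, w))

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """Softmax position weights beta (N, 1, H, W); sums to 1 per image."""
        x = nn.as_tensor(x)
        return self._beta(self._branches(x)).data

    def forward(self, x: Tensor) -> Tensor:
        x = nn.as_tensor(x)
        xprime = self._branches(x)
        beta = self._beta(xprime)
        pooled = core.attention_pool(xprime, beta)            # (N, C)
        ctx = self.s3(core.relu(self.ln(self.s2(pooled))))    # (N, C)
        n, c = ctx.shape
        return x + xprime + core.reshape(ctx, (n, c, 1, 1))


class MPABlock(nn.Module):
    """Multi-scale pyramid aggregation over the five decoder outputs.

    All levels are bilinearly upsampled to the finest (level-0) resolution,
    concatenated and projected to ``fused_channels``; a squeeze-and-excitation
    gate (GAP -> bottleneck -> sigmoid) re-weights the fused channels.
    """

    def __init__(self, config: MPAConfig, rng: np.random.Generator,
                 bias: bool = False, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.config = config
        total = sum(config.level_channels)
        fused = config.fused_channels
        self.project = nn.ConvBNReLU(total, fused, 1, rng, bias=bias, dtype=dtype)
        self.fc1 = nn.Linear(fused, fused // config.se_ratio, rng, dtype=dtype)
        self.fc2 = nn.Linear(fused // config.se_ratio, fused, rng, dtype=dtype)

    def channel_gate(self, g_vec: Tensor) -> Tensor:
        """sigma(M(g, omega)): the squeeze-and-excitation gate in (0, 1)."""
        g_vec = nn.as_tensor(g_vec)
        squeeze = g_vec.ndim == 1
        if squeeze:
            g_vec = core.reshape(g_vec, (1, g_vec.shape[0]))
        if g_vec.shape[-1] != self.config.fused_channels:
            raise ValueError(
                f"expected vectors of length {self.config.fused_channels}, "
                f"got {g_vec.shape[-1]}")
        gate = core.sigmoid(self.fc2(core.relu(self.fc1(g_vec))))
        return core.reshape(gate, (gate.shape[-1],)) if squeeze else gate

    def forward(self, levels: list[Tensor]) -> Tensor:
        if len(levels) != len(self.config.level_channels):
            raise ValueError(
                f"expected {len(self.config.level_channels)} pyramid levels, "
                f"got {len(levels)}")
        levels = [nn.as_tensor(l) for l in levels]
        for i, (l, c) in enumerate(zip(levels, self.config.level_channels)):
            if l.shape[1] != c:
                raise ValueError(f"level {i}: expected {c} channels, got {l.shape[1]}")
        h0, w0 = levels[0].shape[2], levels[0].shape[3]
        for i, l in enumerate(levels[1:], start=1):
            if l.shape[2] > h0 or l.shape[3] > w0:
                raise ValueError(
                    f"level {i} spatial size {l.shape[2:]} exceeds level 0 ({h0}, {w0})")
        aligned = [l if l.shape[2:] == (h0, w0) else core.bilinear_resize(l, h0, w0)
                   for l in levels]
        fused = self.project(core.concat(aligned, axis=1))
        gate = self.channel_gate(core.global_avg_pool(fused))
        n, c = gate.shape
        return fused * core.reshape(gate, (n, c, 1, 1))


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def _apply(block: nn.Module, *args):
    """Run a block on arrays or Tensors, returning the matching type."""
    array_in = not isinstance(args[0], Tensor) and not (
        isinstance(args[0], list) and args[0] and isinstance(args[0][0], Tensor))
    out = block(*args)
    return out.data if array_in else out


def ecc_forward(x, block: ECCBlock):
    """Shape-preserving forward pass of the context-calibrated block."""
    return _apply(block, x)


def context_calibrate(x2, block: ECCBlock):
    """The sigmoid attention map of the calibration path (entries in (0, 1))."""
    out = block.calibrate(nn.as_tensor(x2))
    return out.data if not isinstance(x2, Tensor) else out


def pcf_forward(x, block: PCFBlock):
    """Shape-preserving forward pass of the context-aware fusion block."""
    return _apply(block, x)


def mpa_forward(levels, block: MPABlock):
    """Aggregate five pyramid levels into a fused, channel-gated map."""
    return _apply(block, list(levels))


def se_reweight(g_vec, block: MPABlock):
    """Squeeze-and-excitation gate for a pooled channel vector."""
    out = block.channel_gate(nn.as_tensor(g_vec))
    return out.data if not isinstance(g_vec, Tensor) else out
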