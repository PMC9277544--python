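"""Assembly of the full segmentation network.

A symmetric five-level encoder-decoder. The encoder downsamples by 2x2
max-pooling with depthwise-separable channel transitions; each level's
feature block is either a plain depthwise-separable conv unit (baseline) or
an :class:`~frcnet.blocks.ECCBlock`. The bottleneck optionally applies
:class:`~frcnet.blocks.PCFBlock`. The decoder mirrors the encoder with
bilinear 2x upsampling and *additive* skip connections; the head is either a
1x1 convolution on the finest decoder map or an :class:`~frcnet.blocks.MPABlock`
over all five decoder outputs. A final 1x1 convolution and sigmoid produce a
single-channel probability map at the input resolution.

The default widths (16, 32, 64, 128, 160) keep the full model within the
0.78 M learnable-parameter budget; ``audit_parameter_budget`` checks this.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .nn import Tensor, core
from .nn.modules import DEFAULT_DTYPE
from .blocks import ECCBlock, ECCConfig, PCFBlock, PCFConfig, MPABlock, MPAConfig

__all__ = ["ModelConfig", "FRCNet", "build_frcnet", "count_parameters",
           "PARAM_BUDGET", "VARIANTS"]

VARIANTS = ("baseline", "ecc", "pcf", "mpa", "full")

#: published size of the full model: 0.78 M learnable parameters
PARAM_BUDGET = 780_000


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters and ablation switch.

    ``variant`` selects which context modules are active: ``baseline`` (none),
    ``ecc``/``pcf``/``mpa`` (one each), or ``full`` (all three).
    """

    encoder_widths: tuple[int, ...] = (16, 32, 64, 128, 160)
    variant: str = "full"
    ecc_calibration_rate: int = 4
    ecc_use_depthwise: bool = True
    pcf_dilation: int = 5
    pcf_bottleneck_ratio: int = 4
    mpa_fused_channels: int = 32
    mpa_se_ratio: int = 4
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "encoder_widths", tuple(self.encoder_widths))
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        w = self.encoder_widths
        if len(w) != 5:
            raise ValueError(f"exactly 5 encoder widths required, got {len(w)}")
        if any(b <= a for a, b in zip(w, w[1:])):
            raise ValueError(f"encoder widths must be strictly increasing, got {w}")
        if any(c % 2 for c in w):
            raise ValueError(f"encoder widths must be even, got {w}")

    @property
    def uses_ecc(self) -> bool:
        return self.variant in ("ecc", "full")

    @property
    def uses_pcf(self) -> bool:
        return self.variant in ("pcf", "full")

    @property
    def uses_mpa(self) -> bool:
        return self.variant in ("mpa", "full")

    def to_dict(self) -> dict:
        return {
            "encoder_widths": list(self.encoder_widths),
            "variant": self.variant,
            "ecc_calibration_rate": self.ecc_calibration_rate,
            "ecc_use_depthwise": self.ecc_use_depthwise,
            "pcf_dilation": self.pcf_dilation,
            "pcf_bottleneck_ratio": self.pcf_bottleneck_ratio,
            "mpa_fused_channels": self.mpa_fused_channels,
            "mpa_se_ratio": self.mpa_se_ratio,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**{**d, "encoder_widths": tuple(d["encoder_widths"])})


def _level_rate(cfg: ModelConfig, level: int) -> int:
    # Deep levels see spatial sizes of 2k or 4k pixels for a (32k)-sized
    # input, so the calibration pool factor drops to 2 there to keep the
    # divisibility contract for every multiple-of-32 resolution.
    return min(cfg.ecc_calibration_rate, 2 if level >= 3 else 4)


class FRCNet(nn.Module):
    """Lightweight context-guided encoder-decoder for polyp segmentation."""

    #: spatial granularity the forward contract requires
    SIZE_MULTIPLE = 32

    def __init__(self, config: ModelConfig, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.encoder_widths

        def feature_block(channels: int, level: int) -> nn.Module:
            if config.uses_ecc:
                return ECCBlock(
                    ECCConfig(channels, _level_rate(config, level),
                              config.ecc_use_depthwise), rng, dtype=dtype)
            return nn.DWSeparableConvBNReLU(channels, channels, rng, dtype=dtype)

        self.stem = nn.ConvBNReLU(3, w[0], 3, rng, dtype=dtype)
        for i in range(5):
            if i > 0:
                setattr(self, f"down{i}",
                        nn.DWSeparableConvBNReLU(w[i - 1], w[i], rng, dtype=dtype))
            setattr(self, f"enc{i}", feature_block(w[i], i))

        if config.uses_pcf:
            self.pcf = PCFBlock(
                PCFConfig(w[4], config.pcf_dilation, config.pcf_bottleneck_ratio),
                rng, dtype=dtype)

        for i in range(3, -1, -1):
            setattr(self, f"up{i}",
                    nn.DWSeparableConvBNReLU(w[i + 1], w[i], rng, dtype=dtype))
            setattr(self, f"dec{i}", feature_block(w[i], i))

        if config.uses_mpa:
            self.mpa = MPABlock(
                MPAConfig(tuple(w), config.mpa_fused_channels, config.mpa_se_ratio),
                rng, dtype=dtype)
            head_in = config.mpa_fused_channels
        else:
            head_in = w[0]
        self.head = nn.Conv2d(head_in, 1, 1, rng, bias=True, dtype=dtype)

    def _validate(self, x: Tensor) -> None:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected an (N, 3, H, W) image batch, got {x.shape}")
        n, _, h, w = x.shape
        m = self.SIZE_MULTIPLE
        if h % m or w % m:
            raise ValueError(
                f"input spatial size ({h}, {w}) must be a multiple of {m}; "
                f"pad or resize to the nearest multiple (e.g. "
                f"({-(-h // m) * m}, {-(-w // m) * m}))")

    def forward(self, x) -> Tensor:
        x = nn.as_tensor(x)
        self._validate(x)
        feats = [self.enc0(self.stem(x))]
        for i in range(1, 5):
            pooled = core.max_pool2d(feats[-1], 2)
            feats.append(getattr(self, f"enc{i}")(getattr(self, f"down{i}")(pooled)))

        bottleneck = self.pcf(feats[4]) if self.config.uses_pcf else feats[4]

        decoder = [None] * 5
        decoder[4] = bottleneck
        for i in range(3, -1, -1):
            h, w = feats[i].shape[2], feats[i].shape[3]
            up = core.bilinear_resize(decoder[i + 1], h, w)
            merged = getattr(self, f"up{i}")(up) + feats[i]
            decoder[i] = getattr(self, f"dec{i}")(merged)

        if self.config.uses_mpa:
            fused = self.mpa(decoder)
        else:
            fused = decoder[0]
        # clamp away from exact 0/1 (float32 sigmoid can saturate) so the
        # probability-map contract stays an open interval
        return core.clip(core.sigmoid(self.head(fused)), 1e-6, 1.0 - 1e-6)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Inference-mode probability maps for an (N, 3, H, W) array."""
        was_training = self.training
        self.eval()
        out = self.forward(nn.Tensor(np.asarray(images))).data
        if was_training:
            self.train()
        return out


def build_frcnet(config: ModelConfig, dtype=DEFAULT_DTYPE) -> FRCNet:
    """Build a seeded network; identical configs give bitwise-identical weights."""
    return FRCNet(config, dtype=dtype)


def count_parameters(model: nn.Module) -> int:
    """Exact number of learnable scalar weights in the model."""
    return model.num_parameters()
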