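"""Compound segmentation loss: weighted binary cross-entropy + smoothed Dice.

BCE converges quickly but is sensitive to the foreground/background imbalance
typical of polyp frames; the Dice term directly optimizes region overlap and
counteracts that imbalance. The total loss is

    L = lambda1 * L_BCE + lambda2 * L_Dice,    lambda1 = 0.6, lambda2 = 0.4,

with Laplace smoothing xi = 1e-8 in the Dice ratio. BCE is reduced as the
mean over all pixels of the batch; Dice is computed per image and then
averaged, so frames with small polyps are not swamped by large ones.

All three losses accept either plain numpy arrays (returning a float) or
autodiff tensors (returning a scalar tensor that supports ``backward``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, as_tensor
from .nn import core

__all__ = ["LossWeights", "bce_loss", "dice_loss", "total_loss", "PROB_EPS"]

#: probability clamp applied before logarithms
PROB_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    lambda1: float = 0.6
    lambda2: float = 0.4
    xi: float = 1e-8

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")
        if self.xi <= 0:
            raise ValueError("smoothing factor xi must be positive")


def _prepare(t, that):
    scalar = not isinstance(t, Tensor) and not isinstance(that, Tensor)
    t, that = as_tensor(t), as_tensor(that)
    if t.shape != that.shape:
        raise ValueError(f"mask shape {t.shape} != prediction shape {that.shape}")
    return t, that, scalar


def _flatten_per_image(x: Tensor) -> Tensor:
    """(N, ...) -> (N, P); a bare 1-D input is treated as a single image."""
    if x.ndim <= 1:
        return core.reshape(x, (1, max(1, int(np.prod(x.shape)))))
    return core.reshape(x, (x.shape[0], int(np.prod(x.shape[1:]))))


def bce_loss(t, that):
    """Mean over all pixels of -[t ln p + (1 - t) ln(1 - p)], p clamped to
    [PROB_EPS, 1 - PROB_EPS] for log safety."""
    t, that, scalar = _prepare(t, that)
    p = core.clip(that, PROB_EPS, 1.0 - PROB_EPS)
    ll = t * core.log(p) + (1.0 - t) * core.log(1.0 - p)
    out = -core.mean_(ll)
    return float(out.data) if scalar else out


def dice_loss(t, that, xi: float = 1e-8):
    """1 - (2<t, p> + xi) / (|t| + |p| + xi), per image, averaged over the batch.

    For binary inputs this is 1 - Dice similarity; it lives in [0, 1] and is 0
    exactly when the prediction reproduces the mask (up to xi).
    """
    if xi <= 0:
        raise ValueError("smoothing factor xi must be positive")
    t, that, scalar = _prepare(t, that)
    tf, pf = _flatten_per_image(t), _flatten_per_image(that)
    inter = core.sum_(tf * pf, axis=1)
    denom = core.sum_(tf, axis=1) + core.sum_(pf, axis=1)
    dice = (2.0 * inter + xi) / (denom + xi)
    out = 1.0 - core.mean_(dice)
    return float(out.data) if scalar else out


def total_loss(t, that, weights: LossWeights = LossWeights()):
    """lambda1 * BCE + lambda2 * Dice."""
    t_, that_, scalar = _prepare(t, that)
    out = (weights.lambda1 * bce_loss(t_, that_)
           + weights.lambda2 * dice_loss(t_, that_, weights.xi))
    return float(out.data) if scalar else out
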