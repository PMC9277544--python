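"""Segmentation evaluation: mDice, mIoU, weighted F-measure, S-measure,
mean/max E-measure, and MAE.

Region metrics (Dice, IoU) binarize the predicted probability map at a fixed
threshold (default 0.5). The structure-aware metrics consume the continuous
map, following their source constructions:

* weighted F-measure — precision/recall with dependency-weighted errors:
  false-negative errors are propagated from the nearest foreground pixel and
  smoothed with a 7x7 Gaussian (sigma 5), and background errors are discounted
  by their distance to the object (Margolin et al.'s construction).
* S-measure — alpha-blend of an object-aware term (foreground/background
  mean/spread similarity) and a region-aware term (SSIM-like scores on the
  four quadrants around the ground-truth centroid, area-weighted).
* E-measure — enhanced alignment between the bias-removed prediction and
  ground truth, averaged over the frame, swept over equally spaced
  binarization thresholds; both the mean and the max over thresholds are
  reported.

Degenerate frames are handled explicitly: two empty masks count as a perfect
match (score 1, MAE 0), an empty ground truth with a non-empty prediction
scores 0 on overlap metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

__all__ = ["MetricConfig", "MetricReport", "dice_coef", "iou", "mae",
           "weighted_fmeasure", "s_measure", "e_measure", "evaluate"]

_EPS = np.finfo(np.float64).eps


@dataclass(frozen=True)
class MetricConfig:
    bin_threshold: float = 0.5
    fbw_beta2: float = 1.0
    s_alpha: float = 0.5
    e_thresholds: int = 256

    def __post_init__(self):
        if not 0.0 < self.bin_threshold < 1.0:
            raise ValueError("bin_threshold must lie in (0, 1)")
        if self.e_thresholds < 1:
            raise ValueError("e_thresholds must be positive")


@dataclass
class MetricReport:
    """Mean metrics over a test set, with the per-image values retained."""

    mdice: float
    miou: float
    f_beta_w: float
    s_alpha: float
    mean_e: float
    max_e: float
    mae: float
    per_image: dict[str, list[float]] = field(default_factory=dict, repr=False)

    def to_dict(self, include_per_image: bool = True) -> dict:
        d = {k: v for k, v in asdict(self).items() if k != "per_image"}
        if include_per_image:
            d["per_image"] = self.per_image
        return d


def _check_pair(pred, gt):
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"prediction shape {pred.shape} != mask shape {gt.shape}")
    return pred, gt.astype(bool)


def dice_coef(pred_bin, gt) -> float:
    """2|P∩G| / (|P| + |G|); 1 when both masks are empty."""
    pred, gt = _check_pair(pred_bin, gt)
    p = pred.astype(bool)
    denom = p.sum() + gt.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, gt).sum() / denom)


def iou(pred_bin, gt) -> float:
    """|P∩G| / |P∪G|; 1 when both masks are empty."""
    pred, gt = _check_pair(pred_bin, gt)
    p = pred.astype(bool)
    union = np.logical_or(p, gt).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, gt).sum() / union)


def mae(pred, gt) -> float:
    """Mean absolute pixel error between the probability map and the mask."""
    pred, gt = _check_pair(pred, gt)
    return float(np.abs(pred - gt.astype(np.float64)).mean())


def _matlab_gauss2d(shape=(7, 7), sigma=5.0) -> np.ndarray:
    m, n = [(s - 1.0) / 2.0 for s in shape]
    y, x = np.ogrid[-m:m + 1, -n:n + 1]
    h = np.exp(-(x * x + y * y) / (2.0 * sigma * sigma))
    h[h < np.finfo(h.dtype).eps * h.max()] = 0
    return h / h.sum()


def weighted_fmeasure(pred, gt, cfg: MetricConfig = MetricConfig()) -> float:
    """Dependency-weighted F-measure of a continuous foreground map."""
    pred, gt = _check_pair(pred, gt)
    if not gt.any():
        return 1.0 if pred.max() == 0 else 0.0

    dst, idx = ndimage.distance_transform_edt(~gt, return_indices=True)
    e = np.abs(pred - gt)
    # propagate errors of background pixels from their nearest foreground pixel
    et = e.copy()
    et[~gt] = e[idx[0][~gt], idx[1][~gt]]
    ea = ndimage.convolve(et, _matlab_gauss2d(), mode="constant", cval=0.0)
    min_e_ea = e.copy()
    fg_smooth = gt & (ea < e)
    min_e_ea[fg_smooth] = ea[fg_smooth]
    # pixel importance: background errors decay with distance to the object
    b = np.ones_like(e)
    b[~gt] = 2.0 - np.exp(np.log(0.5) / 5.0 * dst[~gt])
    ew = min_e_ea * b

    tpw = gt.sum() - ew[gt].sum()
    fpw = ew[~gt].sum()
    recall = 1.0 - ew[gt].mean()
    precision = tpw / (tpw + fpw + _EPS)
    beta2 = cfg.fbw_beta2
    q = ((1 + beta2) * recall * precision) / (recall + beta2 * precision + _EPS)
    return float(np.clip(q, 0.0, 1.0))


# -- S-measure --------------------------------------------------------------

def _s_object_part(pred: np.ndarray, region: np.ndarray) -> float:
    if not region.any():
        return 0.0
    x = pred[region].mean()
    sigma_x = pred[region].std()
    return 2.0 * x / (x * x + 1.0 + sigma_x + _EPS)


def _s_object(pred: np.ndarray, gt: np.ndarray) -> float:
    fg = pred.copy()
    fg[~gt] = 0.0
    bg = 1.0 - pred
    bg[gt] = 0.0
    u = gt.mean()
    return u * _s_object_part(fg, gt) + (1.0 - u) * _s_object_part(bg, ~gt)


def _centroid(gt: np.ndarray) -> tuple[int, int]:
    h, w = gt.shape
    if not gt.any():
        return h // 2, w // 2
    rows, cols = np.nonzero(gt)
    return int(round(rows.mean())), int(round(cols.mean()))


def _ssim_like(pred: np.ndarray, gt: np.ndarray) -> float:
    n = pred.size
    if n <= 1:
        return 1.0 if abs(float(pred.mean()) - float(gt.mean())) < _EPS else 0.0
    x, y = pred.mean(), gt.mean()
    sx = ((pred - x) ** 2).sum() / (n - 1)
    sy = ((gt - y) ** 2).sum() / (n - 1)
    sxy = ((pred - x) * (gt - y)).sum() / (n - 1)
    alpha = 4.0 * x * y * sxy
    beta = (x * x + y * y) * (sx + sy)
    if alpha != 0:
        return float(alpha / (beta + _EPS))
    return 1.0 if beta == 0 else 0.0


def _s_region(pred: np.ndarray, gt: np.ndarray) -> float:
    cy, cx = _centroid(gt)
    h, w = gt.shape
    cy = min(max(cy, 1), h - 1)
    cx = min(max(cx, 1), w - 1)
    total = float(h * w)
    score = 0.0
    for rows, cols in (((0, cy), (0, cx)), ((0, cy), (cx, w)),
                       ((cy, h), (0, cx)), ((cy, h), (cx, w))):
        pq = pred[rows[0]:rows[1], cols[0]:cols[1]]
        gq = gt[rows[0]:rows[1], cols[0]:cols[1]].astype(np.float64)
        weight = pq.size / total
        score += weight * _ssim_like(pq, gq)
    return score


def s_measure(pred, gt, cfg: MetricConfig = MetricConfig()) -> float:
    """Structural similarity: alpha * S_object + (1 - alpha) * S_region."""
    pred, gt = _check_pair(pred, gt)
    pred, gt = pred.squeeze(), gt.squeeze()
    if pred.ndim != 2:
        raise ValueError("s_measure expects a single 2-D frame")
    y = gt.mean()
    if y == 0:  # empty ground truth: reward empty predictions
        return float(1.0 - pred.mean())
    if y == 1:  # full-frame object
        return float(pred.mean())
    alpha = cfg.s_alpha
    s = alpha * _s_object(pred, gt) + (1.0 - alpha) * _s_region(pred, gt)
    return float(max(s, 0.0))


# -- E-measure --------------------------------------------------------------

def _alignment_score(fm: np.ndarray, gt: np.ndarray) -> float:
    h, w = gt.shape
    if not gt.any():
        enhanced = 1.0 - fm
    elif gt.all():
        enhanced = fm
    else:
        phi_fm = fm - fm.mean()
        phi_gt = gt.astype(np.float64) - gt.mean()
        align = 2.0 * phi_gt * phi_fm / (phi_gt ** 2 + phi_fm ** 2 + _EPS)
        enhanced = (align + 1.0) ** 2 / 4.0
    # the (HW - 1) normalizer overshoots 1 by 1/(HW-1) on a perfect match;
    # cap so the score stays in [0, 1]
    return float(min(enhanced.sum() / (h * w - 1 + _EPS), 1.0))


def e_measure(pred, gt, cfg: MetricConfig = MetricConfig()) -> tuple[float, float]:
    """(mean, max) enhanced-alignment score over binarization thresholds."""
    pred, gt = _check_pair(pred, gt)
    pred, gt = pred.squeeze(), gt.squeeze()
    if pred.ndim != 2:
        raise ValueError("e_measure expects a single 2-D frame")
    # bin midpoints: equally spaced, strictly inside (0, 1), so the trivial
    # all-foreground binarization at t = 0 is not part of the sweep
    thresholds = (np.arange(cfg.e_thresholds) + 0.5) / cfg.e_thresholds
    scores = np.array([_alignment_score((pred >= t).astype(np.float64), gt)
                       for t in thresholds])
    return float(scores.mean()), float(scores.max())


# -- aggregation ------------------------------------------------------------

def evaluate(preds, gts, cfg: MetricConfig = MetricConfig()) -> MetricReport:
    """Per-image metrics averaged over a paired set of predictions/masks.

    ``preds``/``gts``: sequences (or batched arrays) of equally shaped frames;
    predictions are probability maps in [0, 1], masks binary.
    """
    if len(preds) != len(gts):
        raise ValueError(f"{len(preds)} predictions vs {len(gts)} masks")
    if len(preds) == 0:
        raise ValueError("empty evaluation set")
    per: dict[str, list[float]] = {k: [] for k in
                                   ("dice", "iou", "f_beta_w", "s_alpha",
                                    "mean_e", "max_e", "mae")}
    for pred, gt in zip(preds, gts):
        pred = np.asarray(pred, dtype=np.float64).squeeze()
        gt = np.asarray(gt).squeeze().astype(bool)
        pred_bin = pred >= cfg.bin_threshold
        per["dice"].append(dice_coef(pred_bin, gt))
        per["iou"].append(iou(pred_bin, gt))
        per["f_beta_w"].append(weighted_fmeasure(pred, gt, cfg))
        per["s_alpha"].append(s_measure(pred, gt, cfg))
        me, xe = e_measure(pred, gt, cfg)
        per["mean_e"].append(me)
        per["max_e"].append(xe)
        per["mae"].append(mae(pred, gt))
    return MetricReport(
        mdice=float(np.mean(per["dice"])),
        miou=float(np.mean(per["iou"])),
        f_beta_w=float(np.mean(per["f_beta_w"])),
        s_alpha=float(np.mean(per["s_alpha"])),
        mean_e=float(np.mean(per["mean_e"])),
        max_e=float(np.mean(per["max_e"])),
        mae=float(np.mean(per["mae"])),
        per_image=per,
    )
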