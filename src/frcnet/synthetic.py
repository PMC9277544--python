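"""Seeded generation of colonoscopy-like scenes with exact binary masks.

Each scene is a reddish mucosa-like background — a smooth low-frequency
luminance field plus a few fold-like ridge distractors — on which one or more
polyps are rendered as star-convex blobs: the boundary radius is a periodic
perturbation of a base radius (3-7 lobes), emulating the irregular shapes of
real polyps. The polyp is composited as an intensity offset with a soft
~2-pixel boundary, while the stored mask is the exact unblurred blob support.
Additive Gaussian pixel noise is applied last.

Three challenge regimes can be emulated through the configuration: low
foreground/background contrast (small ``contrast_delta``), small polyps and
large polyps (``radius_frac``). The mixed default covers all three.

Generation is deterministic per (seed, index): every sample derives its RNG
from ``SeedSequence((seed, index))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["SynthConfig", "SamplePair", "GenerationError",
           "generate_sample", "generate_dataset", "augment", "REGIMES"]


class GenerationError(RuntimeError):
    """Raised when a scene cannot be populated within the attempt budget."""


@dataclass(frozen=True)
class SynthConfig:
    """Scene-generator parameters (fractions are relative to the image side)."""

    n_images: int = 200
    size: int = 96
    polyps_per_image: tuple[int, int] = (1, 3)
    radius_frac: tuple[float, float] = (0.06, 0.28)
    contrast_delta: tuple[float, float] = (0.08, 0.5)
    boundary_irregularity: float = 0.3
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.n_images < 1 or self.size < 1:
            raise ValueError("n_images and size must be positive")
        if self.size % 32:
            raise ValueError(f"size must be a multiple of 32, got {self.size}")
        for name in ("polyps_per_image", "radius_frac", "contrast_delta"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range must be ordered (lo <= hi)")
        lo, hi = self.radius_frac
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("radius_frac must lie within (0, 0.5)")
        if self.boundary_irregularity < 0 or self.noise_sigma < 0:
            raise ValueError("irregularity and noise_sigma must be >= 0")


#: named configurations of the three challenge regimes
REGIMES: dict[str, dict] = {
    "mixed": {},
    "low_contrast": {"contrast_delta": (0.03, 0.1)},
    "small": {"radius_frac": (0.04, 0.08), "polyps_per_image": (1, 2)},
    "large": {"radius_frac": (0.25, 0.38), "polyps_per_image": (1, 1)},
}


@dataclass
class SamplePair:
    """One rendered scene: RGB image in [0, 1], exact binary mask, metadata."""

    image: np.ndarray  # (3, H, W) float32 in [0, 1]
    mask: np.ndarray   # (1, H, W) uint8 in {0, 1}
    meta: dict = field(default_factory=dict)


_BASE_COLOR = np.array([0.45, 0.30, 0.25])        # mucosa tint, RGB
_POLYP_TINT = np.array([1.06, 1.0, 0.94])         # polyps slightly pinker; mean 1
_FIELD_AMPLITUDE = 0.15                           # background luminance swing
_BOUNDARY_SIGMA = 1.0                             # ~2 px soft polyp edge


def _bilinear_grid(coarse: np.ndarray, size: int) -> np.ndarray:
    """Upsample a coarse grid to (size, size) with separable linear weights."""
    n = coarse.shape[0]
    src = np.linspace(0, n - 1, size)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n - 1)
    t = src - lo
    rows = coarse[lo][:, :] * (1 - t)[:, None] + coarse[hi][:, :] * t[:, None]
    out = rows[:, lo] * (1 - t)[None, :] + rows[:, hi] * t[None, :]
    return out


def _gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter
    return gaussian_filter(img, sigma=sigma, mode="nearest")


def _background(rng: np.random.Generator, size: int) -> np.ndarray:
    """Smooth reddish field with fold-like ridge distractors, (3, H, W)."""
    coarse = rng.normal(0.0, 1.0, (6, 6))
    lum = _bilinear_grid(coarse, size)
    lum = _FIELD_AMPLITUDE * lum / (np.abs(lum).max() + 1e-9)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    for _ in range(rng.integers(1, 4)):
        theta = rng.uniform(0.0, np.pi)
        offset = rng.uniform(0.2, 0.8) * size
        width = rng.uniform(1.5, 4.0)
        amp = rng.uniform(0.05, 0.12) * rng.choice([-1.0, 1.0])
        dist = (xx * np.cos(theta) + yy * np.sin(theta)) - offset
        lum += amp * np.exp(-0.5 * (dist / width) ** 2)
    channel_scale = 1.0 + rng.uniform(-0.08, 0.08, 3)
    img = (_BASE_COLOR * channel_scale)[:, None, None] + lum[None, :, :]
    return img


def _star_blob(rng: np.random.Generator, size: int, center: tuple[float, float],
               radius: float, irregularity: float) -> np.ndarray:
    """Boolean support of a star-convex blob with 3-7 periodic boundary lobes."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - center[0], xx - center[1]
    dist = np.hypot(dy, dx)
    ang = np.arctan2(dy, dx)
    n_lobes = int(rng.integers(3, 8))
    phases = rng.uniform(0.0, 2 * np.pi, 2)
    amps = rng.uniform(0.3, 1.0, 2)
    amps /= amps.sum() + 1e-9
    perturb = (amps[0] * np.sin(n_lobes * ang + phases[0])
               + amps[1] * np.sin((n_lobes + 2) * ang + phases[1]))
    boundary = radius * (1.0 + irregularity * perturb)
    return dist <= boundary


def generate_sample(cfg: SynthConfig, index: int) -> SamplePair:
    """Render scene ``index`` of the configured dataset (deterministic)."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed & 0x7FFFFFFF, index)))
    size = cfg.size
    image = _background(rng, size)
    mask = np.zeros((size, size), dtype=bool)

    n_polyps = int(rng.integers(cfg.polyps_per_image[0], cfg.polyps_per_image[1] + 1))
    centers, radii, deltas = [], [], []
    offset = np.zeros((size, size))
    for _ in range(n_polyps):
        placed = False
        for _attempt in range(100):
            radius = rng.uniform(*cfg.radius_frac) * size
            margin = radius * (1.0 + cfg.boundary_irregularity) + 2.0
            if 2 * margin >= size:
                continue
            cy = rng.uniform(margin, size - margin)
            cx = rng.uniform(margin, size - margin)
            support = _star_blob(rng, size, (cy, cx), radius,
                                 cfg.boundary_irregularity)
            if (mask | support).mean() >= 0.6:
                continue
            delta = rng.uniform(*cfg.contrast_delta)
            # full offset on the support, feathered halo just outside it;
            # overlapping polyps composite by maximum, not by summation
            soft = np.maximum(support,
                              _gaussian_blur(support.astype(np.float64),
                                             _BOUNDARY_SIGMA))
            offset = np.maximum(offset, delta * soft)
            mask |= support
            centers.append((float(cy), float(cx)))
            radii.append(float(radius))
            deltas.append(float(delta))
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place polyp in sample {index} within 100 attempts")
    image += offset[None, :, :] * _POLYP_TINT[:, None, None]

    if cfg.noise_sigma > 0:
        image += rng.normal(0.0, cfg.noise_sigma, image.shape)
    image = np.clip(image, 0.0, 1.0)
    meta = {"index": index, "centers": centers, "radii": radii,
            "contrast": deltas, "n_polyps": n_polyps}
    return SamplePair(image=image.astype(np.float32),
                      mask=mask[None, :, :].astype(np.uint8), meta=meta)


def generate_dataset(cfg: SynthConfig, out_dir) -> dict:
    """Write ``cfg.n_images`` image/mask PNG pairs plus a JSON manifest.

    Layout: ``out_dir/images/NNNN.png`` (RGB), ``out_dir/masks/NNNN.png``
    (8-bit gray, 0/255), ``out_dir/manifest.json``. Re-running with the same
    configuration reproduces byte-identical files.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(cfg.n_images):
        pair = generate_sample(cfg, i)
        name = f"{i:04d}.png"
        rgb = np.moveaxis((pair.image * 255.0).round().astype(np.uint8), 0, -1)
        Image.fromarray(rgb, mode="RGB").save(out_dir / "images" / name)
        Image.fromarray(pair.mask[0] * 255, mode="L").save(out_dir / "masks" / name)
        entries.append({"file": name, **pair.meta})
    manifest = {"config": asdict(cfg), "samples": entries}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def augment(pair: SamplePair, rng: np.random.Generator) -> SamplePair:
    """Random flips, 90-degree rotations, and photometric jitter.

    Each transform is applied with probability 0.5: horizontal flip, vertical
    flip, a k*90-degree rotation (k uniform in {0..3}), a brightness scale in
    [0.8, 1.2], and a contrast scale in [0.8, 1.2]. Geometric transforms are
    applied identically to image and mask; photometric jitter touches the
    image only and the mask stays binary throughout.
    """
    image, mask = pair.image, pair.mask
    if rng.random() < 0.5:
        image, mask = image[..., ::-1], mask[..., ::-1]
    if rng.random() < 0.5:
        image, mask = image[..., ::-1, :], mask[..., ::-1, :]
    if rng.random() < 0.5:
        k = int(rng.integers(0, 4))
        image = np.rot90(image, k, axes=(-2, -1))
        mask = np.rot90(mask, k, axes=(-2, -1))
    if rng.random() < 0.5:
        image = image * rng.uniform(0.8, 1.2)
    if rng.random() < 0.5:
        scale = rng.uniform(0.8, 1.2)
        mean = image.mean()
        image = (image - mean) * scale + mean
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return SamplePair(image=np.ascontiguousarray(image),
                      mask=np.ascontiguousarray(mask), meta=dict(pair.meta))
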