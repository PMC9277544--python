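"""Determinism, regime coverage, and geometric consistency of the scene
generator and augmentation pipeline."""

import json
from pathlib import Path

import numpy as np
import pytest
from PIL import Image
from skimage.filters import threshold_otsu

from frcnet.metrics import dice_coef
from frcnet.synthetic import (REGIMES, SamplePair, SynthConfig, augment,
                              generate_dataset, generate_sample)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SynthConfig(size=50)  # not a multiple of 32
    with pytest.raises(ValueError):
        SynthConfig(radius_frac=(0.3, 0.1))  # unordered range
    with pytest.raises(ValueError):
        SynthConfig(radius_frac=(0.2, 0.6))  # outside (0, 0.5)
    with pytest.raises(ValueError):
        SynthConfig(noise_sigma=-0.1)


def test_generation_is_bitwise_deterministic_per_seed_and_index():
    cfg = SynthConfig(n_images=5, size=64, seed=7)
    a, b = generate_sample(cfg, 3), generate_sample(cfg, 3)
    assert np.array_equal(a.image, b.image)
    assert np.array_equal(a.mask, b.mask)
    c = generate_sample(cfg, 4)
    assert not np.array_equal(a.image, c.image)
    d = generate_sample(SynthConfig(n_images=5, size=64, seed=8), 3)
    assert not np.array_equal(a.image, d.image)


def test_sample_contracts():
    cfg = SynthConfig(n_images=3, size=64, seed=0)
    for i in range(3):
        s = generate_sample(cfg, i)
        assert s.image.shape == (3, 64, 64)
        assert s.mask.shape == (1, 64, 64)
        assert s.image.min() >= 0.0 and s.image.max() <= 1.0
        assert set(np.unique(s.mask)) <= {0, 1}
        frac = s.mask.mean()
        assert 0.0 < frac < 0.6
        assert len(s.meta["radii"]) == s.meta["n_polyps"] >= 1


def test_configured_contrast_is_recovered_from_rendered_scenes():
    cfg = SynthConfig(n_images=1, size=96, seed=1,
                      contrast_delta=(0.5, 0.5), noise_sigma=0.0)
    gaps = []
    for i in range(5):
        s = generate_sample(cfg, i)
        fg = s.image[:, s.mask[0] > 0].mean()
        bg = s.image[:, s.mask[0] == 0].mean()
        gaps.append(fg - bg)
    assert abs(np.mean(gaps) - 0.5) < 0.05


def test_single_small_polyp_area_matches_disk_area():
    cfg = SynthConfig(n_images=1, size=96, seed=2, polyps_per_image=(1, 1),
                      radius_frac=(0.05, 0.05))
    areas = [generate_sample(cfg, i).mask.mean() for i in range(5)]
    disk = np.pi * 0.05 ** 2
    for a in areas:
        assert 0.5 * disk < a < 2.0 * disk


def test_mean_radius_matches_configured_midpoint():
    cfg = SynthConfig(n_images=200, size=96, seed=0, radius_frac=(0.06, 0.28))
    radii = [r for i in range(200) for r in generate_sample(cfg, i).meta["radii"]]
    mid = 0.5 * (0.06 + 0.28) * 96
    assert abs(np.mean(radii) - mid) / mid < 0.05


def test_low_contrast_regime_defeats_threshold_baseline():
    """The hard regime must exist: with contrast <= 0.1 an Otsu luminance
    threshold fails (mean Dice <= 0.5) even though the mask is exact."""
    cfg = SynthConfig(n_images=1, size=96, seed=3, **REGIMES["low_contrast"])
    scores = []
    for i in range(20):
        s = generate_sample(cfg, i)
        lum = s.image.mean(axis=0)
        scores.append(dice_coef(lum > threshold_otsu(lum), s.mask[0] > 0))
    assert np.mean(scores) <= 0.5


def test_dataset_writer_layout_and_reproducibility(tmp_path):
    cfg = SynthConfig(n_images=10, size=64, seed=5)
    manifest = generate_dataset(cfg, tmp_path / "a")
    assert len(manifest["samples"]) == 10
    imgs = sorted((tmp_path / "a" / "images").glob("*.png"))
    masks = sorted((tmp_path / "a" / "masks").glob("*.png"))
    assert len(imgs) == len(masks) == 10
    assert (tmp_path / "a" / "manifest.json").exists()
    # masks decode to {0, 255} only
    vals = np.unique(np.asarray(Image.open(masks[0])))
    assert set(vals) <= {0, 255}
    # regeneration is byte-identical
    generate_dataset(cfg, tmp_path / "b")
    for sub in ("images", "masks"):
        for f in sorted((tmp_path / "a" / sub).glob("*.png")):
            assert f.read_bytes() == (tmp_path / "b" / sub / f.name).read_bytes()
    assert (json.loads((tmp_path / "a" / "manifest.json").read_text())
            == json.loads((tmp_path / "b" / "manifest.json").read_text()))


# -- augmentation -------------------------------------------------------------

class _Forced:
    """Minimal rng standing in for default_rng: forces chosen branches."""

    def __init__(self, decisions, k=0):
        self.decisions = list(decisions)
        self.k = k

    def random(self):
        return self.decisions.pop(0)

    def integers(self, lo, hi):
        return self.k

    def uniform(self, lo, hi):
        return (lo + hi) / 2.0


def test_double_horizontal_flip_is_identity():
    pair = generate_sample(SynthConfig(n_images=1, size=64, seed=1), 0)
    once = augment(pair, _Forced([0.0, 1.0, 1.0, 1.0, 1.0]))
    twice = augment(once, _Forced([0.0, 1.0, 1.0, 1.0, 1.0]))
    np.testing.assert_array_equal(twice.image, pair.image)
    np.testing.assert_array_equal(twice.mask, pair.mask)


def test_augment_preserves_mask_binarity_and_foreground_count(rng):
    pair = generate_sample(SynthConfig(n_images=1, size=64, seed=2), 0)
    for _ in range(10):
        out = augment(pair, rng)
        assert set(np.unique(out.mask)) <= {0, 1}
        assert out.mask.sum() == pair.mask.sum()
        assert out.image.shape == pair.image.shape


def test_augment_is_reproducible_with_seeded_rng():
    pair = generate_sample(SynthConfig(n_images=1, size=64, seed=3), 0)
    a = augment(pair, np.random.default_rng(42))
    b = augment(pair, np.random.default_rng(42))
    assert np.array_equal(a.image, b.image)
    assert np.array_equal(a.mask, b.mask)


def test_centroid_transforms_exactly_with_geometry():
    pair = generate_sample(SynthConfig(n_images=1, size=64, seed=4,
                                       polyps_per_image=(1, 1)), 0)
    h = pair.mask.shape[-1]

    def centroid(mask):
        rows, cols = np.nonzero(mask[0])
        return rows.mean(), cols.mean()

    cy, cx = centroid(pair.mask)
    hflip = augment(pair, _Forced([0.0, 1.0, 1.0, 1.0, 1.0]))
    assert centroid(hflip.mask) == pytest.approx((cy, h - 1 - cx))
    vflip = augment(pair, _Forced([1.0, 0.0, 1.0, 1.0, 1.0]))
    assert centroid(vflip.mask) == pytest.approx((h - 1 - cy, cx))
    rot90 = augment(pair, _Forced([1.0, 1.0, 0.0, 1.0, 1.0], k=1))
    assert centroid(rot90.mask) == pytest.approx((h - 1 - cx, cy))
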