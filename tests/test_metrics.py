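"""Fixpoints, hand counts, identities and loop-oracle checks for the
seven-statistic evaluation suite."""

import numpy as np
import pytest

from frcnet.metrics import (MetricConfig, dice_coef, e_measure, evaluate, iou,
                            mae, s_measure, weighted_fmeasure)


def _blob_mask(h=16, w=16):
    g = np.zeros((h, w))
    g[3:9, 4:10] = 1
    g[10:13, 11:14] = 1
    return g


def _soft_pred(rng, gt):
    p = np.clip(gt * 0.8 + rng.uniform(0.0, 0.25, gt.shape), 0, 1)
    return p


# -- hand counts --------------------------------------------------------------

def test_dice_and_iou_hand_counts():
    p = np.array([1, 1, 0, 0], dtype=float)
    g = np.array([1, 0, 1, 0], dtype=float)
    assert dice_coef(p, g) == pytest.approx(0.5)
    assert iou(p, g) == pytest.approx(1.0 / 3.0)
    assert dice_coef(np.zeros(4), np.zeros(4)) == 1.0
    assert iou(np.zeros(4), np.zeros(4)) == 1.0
    assert dice_coef(np.array([1, 1, 0, 0.]), np.array([0, 0, 1, 1.])) == 0.0


def test_mae_hand_values(rng):
    g = _blob_mask()
    assert mae(g, g) == 0.0
    assert mae(1.0 - g, g) == 1.0
    p = g.copy()
    half = np.zeros_like(g, dtype=bool)
    half[:8] = True
    p[half] = np.clip(g[half] + 0.5 * np.where(g[half] > 0, -1, 1), 0, 1)
    assert mae(p, g) == pytest.approx(0.25)


# -- fixpoints and degenerate frames ------------------------------------------

def test_perfect_prediction_fixpoints():
    g = _blob_mask()
    assert dice_coef(g, g) == 1.0
    assert iou(g, g) == 1.0
    assert weighted_fmeasure(g, g) == pytest.approx(1.0)
    assert s_measure(g, g) == pytest.approx(1.0, abs=1e-9)
    me, xe = e_measure(g, g)
    assert me == pytest.approx(1.0) and xe == pytest.approx(1.0)
    assert mae(g, g) == 0.0


def test_inverted_prediction_scores_lowest():
    g = _blob_mask()
    # the Gaussian error smoothing leaves a residual of order 1e-3
    assert weighted_fmeasure(1.0 - g, g) == pytest.approx(0.0, abs=0.01)
    assert s_measure(1.0 - g, g) < s_measure(g, g)


def test_empty_ground_truth_conventions():
    empty = np.zeros((8, 8))
    assert weighted_fmeasure(empty, empty) == 1.0
    assert weighted_fmeasure(np.ones((8, 8)), empty) == 0.0
    assert s_measure(empty, empty) == pytest.approx(1.0)


def test_constant_prediction_scores_below_exact_structure(rng):
    g = _blob_mask()
    const = np.full_like(g, g.mean())
    assert s_measure(const, g) < s_measure(g, g)


# -- identities and orderings --------------------------------------------------

def test_dice_jaccard_identity_per_image(rng):
    for seed in range(5):
        r = np.random.default_rng(seed)
        p = (r.random((12, 12)) > 0.6).astype(float)
        g = (r.random((12, 12)) > 0.5).astype(float)
        d, j = dice_coef(p, g), iou(p, g)
        assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)


def test_max_e_dominates_mean_e_and_threshold_consistency(rng):
    g = _blob_mask()
    p = _soft_pred(rng, g)
    me, xe = e_measure(p, g)
    assert xe >= me
    single = MetricConfig(e_thresholds=1)  # lone midpoint threshold = 0.5
    me_05, _ = e_measure(p, g, single)
    assert xe >= me_05 - 1e-12


def test_weighted_fmeasure_prefers_near_misses():
    g = np.zeros((12, 12))
    g[4:7, 4:7] = 1
    near, far = np.roll(g, 1, axis=1), np.roll(g, 5, axis=1)
    assert weighted_fmeasure(near, g) > weighted_fmeasure(far, g)


def test_flip_invariance_of_all_metrics(rng):
    g = _blob_mask()
    p = _soft_pred(rng, g)
    cfg = MetricConfig(e_thresholds=32)

    def all7(pp, gg):
        me, xe = e_measure(pp, gg, cfg)
        return (dice_coef(pp >= 0.5, gg), iou(pp >= 0.5, gg), mae(pp, gg),
                weighted_fmeasure(pp, gg, cfg), s_measure(pp, gg, cfg), me, xe)

    base = all7(p, g)
    for flip in (np.fliplr, np.flipud):
        flipped = all7(flip(p), flip(g))
        # dice/iou/mae and both E statistics are exactly flip-invariant
        np.testing.assert_allclose(flipped[:3], base[:3], atol=1e-12)
        np.testing.assert_allclose(flipped[5:], base[5:], atol=1e-12)
        # F^w and S depend on distance-transform tie-breaks and the centroid
        # quadrant split, so flips agree only approximately
        np.testing.assert_allclose(flipped[3:5], base[3:5], atol=0.02)


def test_pixel_metrics_invariant_under_common_permutation(rng):
    g = (rng.random(64) > 0.6).astype(float)
    p = rng.random(64)
    perm = rng.permutation(64)
    assert mae(p[perm], g[perm]) == pytest.approx(mae(p, g), abs=1e-12)
    assert dice_coef(p[perm] >= 0.5, g[perm]) == dice_coef(p >= 0.5, g)
    assert iou(p[perm] >= 0.5, g[perm]) == iou(p >= 0.5, g)


# -- loop oracles --------------------------------------------------------------

def test_e_measure_matches_explicit_alignment_formula(rng):
    g = _blob_mask(8, 8)
    p = _soft_pred(rng, g)
    cfg = MetricConfig(e_thresholds=1)  # single threshold at 0.5
    me, xe = e_measure(p, g, cfg)

    fm = (p >= 0.5).astype(float)
    h, w = g.shape
    mu_fm, mu_gt = fm.mean(), g.mean()
    acc = 0.0
    for i in range(h):
        for j in range(w):
            pf = fm[i, j] - mu_fm
            pg = g[i, j] - mu_gt
            align = 2 * pg * pf / (pg * pg + pf * pf + np.finfo(float).eps)
            acc += (align + 1.0) ** 2 / 4.0
    expected = min(acc / (h * w - 1), 1.0)
    assert me == pytest.approx(expected, abs=1e-12)
    assert xe == pytest.approx(expected, abs=1e-12)


def test_s_measure_matches_direct_transcription(rng):
    g = _blob_mask().astype(bool)
    p = _soft_pred(rng, g.astype(float))
    eps = np.finfo(np.float64).eps

    # object-aware term
    def obj(vals):
        if vals.size == 0:
            return 0.0
        x, s = vals.mean(), vals.std()
        return 2 * x / (x * x + 1 + s + eps)

    mu = g.mean()
    s_obj = mu * obj(p[g]) + (1 - mu) * obj((1.0 - p)[~g])

    # region-aware term: quadrants around the mask centroid
    rows, cols = np.nonzero(g)
    cy, cx = int(round(rows.mean())), int(round(cols.mean()))
    h, w = g.shape
    s_reg = 0.0
    for rs, cs in (((0, cy), (0, cx)), ((0, cy), (cx, w)),
                   ((cy, h), (0, cx)), ((cy, h), (cx, w))):
        pq = p[rs[0]:rs[1], cs[0]:cs[1]]
        gq = g[rs[0]:rs[1], cs[0]:cs[1]].astype(float)
        n = pq.size
        x, y = pq.mean(), gq.mean()
        sx = ((pq - x) ** 2).sum() / (n - 1)
        sy = ((gq - y) ** 2).sum() / (n - 1)
        sxy = ((pq - x) * (gq - y)).sum() / (n - 1)
        alpha, beta = 4 * x * y * sxy, (x * x + y * y) * (sx + sy)
        q = alpha / (beta + eps) if alpha != 0 else (1.0 if beta == 0 else 0.0)
        s_reg += (n / (h * w)) * q

    expected = max(0.5 * s_obj + 0.5 * s_reg, 0.0)
    assert s_measure(p, g) == pytest.approx(expected, abs=1e-10)


# -- aggregation ---------------------------------------------------------------

def test_evaluate_reports_means_and_preserves_inequality(rng):
    gts = [_blob_mask(), np.roll(_blob_mask(), 3, axis=0), _blob_mask(12, 16)]
    preds = [_soft_pred(rng, g) for g in gts]
    cfg = MetricConfig(e_thresholds=16)
    report = evaluate(preds, gts, cfg)
    for name in ("mdice", "miou", "f_beta_w", "s_alpha", "mean_e", "max_e", "mae"):
        assert 0.0 <= getattr(report, name) <= 1.0
    assert report.mdice >= report.miou
    for d, j in zip(report.per_image["dice"], report.per_image["iou"]):
        assert d >= j

    perfect = evaluate(gts, gts, cfg)
    assert perfect.mdice == perfect.miou == 1.0
    assert perfect.mae == 0.0
    assert perfect.f_beta_w == pytest.approx(1.0)
    assert perfect.mean_e == pytest.approx(1.0)

    single = evaluate(preds[:1], gts[:1], cfg)
    assert single.mdice == pytest.approx(single.per_image["dice"][0])


def test_evaluate_rejects_mismatched_sets(rng):
    g = _blob_mask()
    with pytest.raises(ValueError):
        evaluate([g, g], [g], MetricConfig())
    with pytest.raises(ValueError):
        evaluate([], [], MetricConfig())
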