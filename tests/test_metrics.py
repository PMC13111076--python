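"""Losses and metric suite against hand counts and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from rtsnet import nn
from rtsnet.errors import ShapeError, UndefinedMetricError
from rtsnet.metrics import (ConfusionCounts, accuracy, auc, confusion,
                            dice_coef, dice_loss, evaluate_metrics, f1, hd95,
                            iou, precision, recall, total_loss)


# --------------------------------------------------------------------------
# dice loss
# --------------------------------------------------------------------------

def test_dice_loss_analytic_cases():
    g = np.zeros((6, 6))
    g[:3] = 1
    assert dice_loss(g, g, eps=0.0) == pytest.approx(0.0)
    disjoint = 1 - g
    assert dice_loss(disjoint, g, eps=0.0) == pytest.approx(1.0)
    half = np.full((6, 6), 0.5)
    assert dice_loss(half, g, eps=0.0) == pytest.approx(0.5)


def test_dice_loss_shape_mismatch():
    with pytest.raises(ShapeError):
        dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))


def test_dice_loss_matches_on_tensor_and_array_paths():
    rng = np.random.default_rng(0)
    p = rng.random((5, 5))
    g = (rng.random((5, 5)) > 0.5).astype(float)
    assert float(dice_loss(nn.Tensor(p), g).data) == pytest.approx(
        dice_loss(p, g), abs=1e-6)


def test_total_loss_equal_heads_and_mixed_heads():
    g = np.zeros((1, 1, 4, 4), dtype=np.float32)
    g[0, 0, :2] = 1
    # identical heads -> mean equals the single-head loss
    logit = nn.Tensor(np.random.default_rng(1).normal(size=(1, 1, 4, 4)))
    tl = float(total_loss([logit] * 4, nn.Tensor(g)).data)
    single = dice_loss(1 / (1 + np.exp(-logit.data)), g)
    assert tl == pytest.approx(single, abs=1e-6)
    # one perfect head, three empty-prediction heads -> (0 + 3) / 4
    big = 60.0
    perfect = nn.Tensor(np.where(g > 0, big, -big))
    empty = nn.Tensor(np.full_like(g, -big))
    tl = float(total_loss([perfect, empty, empty, empty], nn.Tensor(g)).data)
    assert tl == pytest.approx(0.75, abs=1e-4)


def test_total_loss_matches_per_head_loop():
    rng = np.random.default_rng(2)
    g = (rng.random((2, 1, 8, 8)) > 0.6).astype(np.float32)
    heads = [nn.Tensor(rng.normal(size=(2, 1, 8, 8))) for _ in range(4)]
    tl = float(total_loss(heads, nn.Tensor(g)).data)
    ref = np.mean([dice_loss(1 / (1 + np.exp(-h.data)), g) for h in heads])
    assert tl == pytest.approx(ref, abs=1e-6)


# --------------------------------------------------------------------------
# confusion counts
# --------------------------------------------------------------------------

def test_confusion_hand_counted_toy():
    g = np.zeros((4, 4), dtype=int)
    g[0, 0] = g[0, 1] = g[1, 0] = g[1, 1] = 1          # 4 foreground pixels
    pred = np.zeros((4, 4), dtype=int)
    pred[0, 0] = pred[0, 1] = 1                        # overlaps 2
    pred[3, 3] = 1                                     # adds 1
    c = confusion(pred, g)
    assert (c.TP, c.FN, c.FP, c.TN) == (2, 2, 1, 11)


def test_confusion_identity_and_complement():
    g = (np.random.default_rng(0).random((8, 8)) > 0.5).astype(int)
    c = confusion(g, g)
    assert c.FP == 0 and c.FN == 0
    c2 = confusion(1 - g, g)
    assert c2.TP == 0 and c2.TN == 0


def test_confusion_rejects_non_binary():
    with pytest.raises(ValueError):
        confusion(np.full((2, 2), 0.5), np.zeros((2, 2)))


def test_count_metric_formulas():
    c = ConfusionCounts(TP=2, FP=1, FN=2, TN=11)
    assert iou(c) == pytest.approx(0.4)
    assert dice_coef(c) == pytest.approx(4 / 7)
    assert accuracy(c) == pytest.approx(13 / 16)
    assert recall(c) == pytest.approx(0.5)
    assert precision(c) == pytest.approx(2 / 3)


def test_empty_union_convention():
    c = ConfusionCounts(0, 0, 0, 10)
    assert iou(c) == dice_coef(c) == f1(c) == precision(c) == recall(c) == 1.0
    c2 = ConfusionCounts(0, 3, 0, 7)   # prediction nonempty, truth empty
    assert iou(c2) == 0.0 and recall(c2) == 0.0


@given(st.tuples(st.integers(0, 500), st.integers(0, 500),
                 st.integers(0, 500), st.integers(0, 500)))
@settings(max_examples=200, derandomize=True)
def test_dice_equals_f1_and_dominates_iou(counts):
    c = ConfusionCounts(*counts)
    assert dice_coef(c) == pytest.approx(f1(c), abs=1e-12)
    assert iou(c) <= dice_coef(c) + 1e-12
    assert 0.0 <= accuracy(c) <= 1.0


def test_dice_loss_dice_coef_duality_for_binary_predictions():
    rng = np.random.default_rng(3)
    for _ in range(20):
        p = (rng.random((10, 10)) > 0.5).astype(int)
        g = (rng.random((10, 10)) > 0.5).astype(int)
        if p.sum() + g.sum() == 0:
            continue
        assert dice_loss(p, g, eps=0.0) == pytest.approx(
            1.0 - dice_coef(confusion(p, g)), abs=1e-12)


# --------------------------------------------------------------------------
# HD95
# --------------------------------------------------------------------------

def oracle_boundary(mask):
    """Explicit 4-neighbourhood boundary scan (image border = background)."""
    H, W = mask.shape
    pts = []
    for y in range(H):
        for x in range(W):
            if not mask[y, x]:
                continue
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                yy, xx = y + dy, x + dx
                if not (0 <= yy < H and 0 <= xx < W) or not mask[yy, xx]:
                    pts.append((y, x))
                    break
    return np.array(pts, dtype=float).reshape(-1, 2)


def oracle_hd95(pred, g):
    """All-pairs boundary-distance 95th percentile."""
    bp, bg = oracle_boundary(pred), oracle_boundary(g)
    d = cdist(bp, bg)
    return max(np.percentile(d.min(axis=1), 95),
               np.percentile(d.min(axis=0), 95))


def test_hd95_identity_and_singletons():
    g = np.zeros((16, 16), dtype=int)
    g[4:8, 4:8] = 1
    assert hd95(g, g) == 0.0
    a = np.zeros((12, 12), dtype=int)
    b = np.zeros((12, 12), dtype=int)
    a[6, 2] = 1
    b[6, 7] = 1
    assert hd95(a, b) == pytest.approx(5.0)


def test_hd95_empty_mask_conventions():
    empty = np.zeros((10, 10), dtype=int)
    full = np.zeros((10, 10), dtype=int)
    full[2:4, 2:4] = 1
    assert hd95(empty, empty) == 0.0
    assert hd95(full, empty) == pytest.approx(np.hypot(10, 10))
    assert hd95(empty, full) == pytest.approx(np.hypot(10, 10))


def test_hd95_shifted_square_matches_all_pairs_oracle():
    a = np.zeros((32, 32), dtype=int)
    b = np.zeros((32, 32), dtype=int)
    a[10:20, 10:20] = 1
    b[13:23, 10:20] = 1
    assert hd95(a, b) == pytest.approx(oracle_hd95(a, b))


def test_hd95_random_masks_match_oracle():
    rng = np.random.default_rng(4)
    for _ in range(10):
        a = (rng.random((14, 14)) > 0.7).astype(int)
        b = (rng.random((14, 14)) > 0.7).astype(int)
        if not a.any() or not b.any():
            continue
        assert hd95(a, b) == pytest.approx(oracle_hd95(a, b), abs=1e-9)


def test_hd95_translation_invariance():
    a = np.zeros((24, 24), dtype=int)
    b = np.zeros((24, 24), dtype=int)
    a[4:9, 4:9] = 1
    b[6:11, 5:10] = 1
    shifted = (np.roll(np.roll(a, 5, axis=0), 5, axis=1),
               np.roll(np.roll(b, 5, axis=0), 5, axis=1))
    assert hd95(a, b) == pytest.approx(hd95(*shifted))


# --------------------------------------------------------------------------
# AUC
# --------------------------------------------------------------------------

def oracle_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return conc / (len(pos) * len(neg))


def test_auc_conventions_and_oracle():
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    assert auc(np.array([.1, .2, .3, .4, .6, .7, .8, .9]), y) == 1.0
    assert auc(np.full(8, 0.5), y) == 0.5
    s = np.array([.3, .8, .5, .5, .5, .9, .2, .7])
    assert auc(s, y) == pytest.approx(oracle_auc(s, y))


def test_auc_monotone_invariance_and_sklearn_agreement():
    from sklearn.metrics import roc_auc_score
    rng = np.random.default_rng(5)
    s = rng.random(200)
    y = (rng.random(200) > 0.6).astype(int)
    a = auc(s, y)
    assert a == pytest.approx(auc(np.exp(3 * s), y))     # strictly monotone
    assert a == pytest.approx(roc_auc_score(y, s))


def test_auc_single_class_raises():
    with pytest.raises(UndefinedMetricError):
        auc(np.array([0.1, 0.9]), np.array([1, 1]))


# --------------------------------------------------------------------------
# report assembly
# --------------------------------------------------------------------------

def test_perfect_predictions_score_perfectly(tmp_path):
    rng = np.random.default_rng(6)
    gts = [(rng.random((12, 12)) > 0.6).astype(np.uint8) for _ in range(3)]
    report = evaluate_metrics([g.astype(float) for g in gts], gts)
    for mode in ("mean_per_image", "pooled"):
        agg = report.aggregates[mode]
        assert agg["iou"] == 1.0 and agg["dice"] == 1.0 and agg["f1"] == 1.0
    assert report.aggregates["mean_per_image"]["hd95"] == 0.0
    report.to_csv(tmp_path / "m.csv")
    report.to_json(tmp_path / "m.json")
    assert (tmp_path / "m.csv").exists() and (tmp_path / "m.json").exists()


def test_pooled_f1_differs_from_mean_dice_in_general():
    g1 = np.zeros((8, 8), dtype=np.uint8)
    g1[:4] = 1
    g2 = np.zeros((8, 8), dtype=np.uint8)
    g2[0, 0] = 1
    p1 = np.zeros((8, 8))
    p1[:4, :4] = 1.0
    p2 = np.zeros((8, 8))
    report = evaluate_metrics([p1, p2], [g1, g2])
    mean_dice = report.aggregates["mean_per_image"]["dice"]
    pooled_f1 = report.aggregates["pooled"]["f1"]
    assert mean_dice != pytest.approx(pooled_f1)
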