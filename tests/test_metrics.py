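"""Evaluation metrics: confusion counts, F1/Dice identity, BLE, CDR."""

import numpy as np
import pytest

from fundusseg.metrics import (
    ConfusionCounts,
    ble,
    cdr,
    confusion,
    contour_radii,
    dice,
    evaluate_masks,
    f1_score,
    precision_recall,
)
from fundusseg.synthetic import SceneParams, make_sample


def _disk(size, center, radius):
    rr, cc = np.mgrid[0:size, 0:size]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


# -- confusion ----------------------------------------------------------------

def test_confusion_identity_case():
    gt = np.zeros(100, dtype=bool)
    gt[:50] = True
    c = confusion(gt.reshape(10, 10), gt.reshape(10, 10))
    assert (c.tp, c.tn, c.fp, c.fn) == (50, 50, 0, 0)


def test_confusion_saturated_prediction():
    gt = np.zeros((10, 10), dtype=bool)
    gt.flat[:10] = True
    c = confusion(np.ones((10, 10), dtype=bool), gt)
    assert (c.tp, c.fp, c.fn, c.tn) == (10, 90, 0, 0)


def test_confusion_matches_loop_oracle(rng):
    for _ in range(100):
        pred = rng.uniform(size=(8, 8)) > 0.5
        gt = rng.uniform(size=(8, 8)) > 0.5
        c = confusion(pred, gt)
        tp = fp = fn = tn = 0
        for i in range(8):
            for j in range(8):
                if pred[i, j] and gt[i, j]:
                    tp += 1
                elif pred[i, j]:
                    fp += 1
                elif gt[i, j]:
                    fn += 1
                else:
                    tn += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
        assert c.total == 64


def test_confusion_rejects_shape_mismatch():
    with pytest.raises(ValueError):
        confusion(np.ones((2, 2), bool), np.ones((3, 3), bool))


# -- F1 / Dice ----------------------------------------------------------------

def test_f1_and_dice_hand_computation():
    c = ConfusionCounts(tp=8, fp=2, fn=2, tn=88)
    p, r = precision_recall(c)
    assert (p, r) == (0.8, 0.8)
    assert abs(f1_score(c) - 0.8) < 1e-12
    assert abs(dice(c) - 16 / 20) < 1e-12


def test_perfect_prediction_scores_one():
    c = ConfusionCounts(tp=10, fp=0, fn=0, tn=90)
    assert f1_score(c) == dice(c) == 1.0


def test_empty_mask_conventions():
    both_empty = ConfusionCounts(0, 0, 0, 100)
    one_empty = ConfusionCounts(0, 0, 5, 95)
    assert f1_score(both_empty) == dice(both_empty) == 1.0
    assert f1_score(one_empty) == dice(one_empty) == 0.0


def test_f1_equals_dice_on_random_pairs(rng):
    for _ in range(500):
        pred = rng.uniform(size=(4, 4)) > rng.uniform()
        gt = rng.uniform(size=(4, 4)) > rng.uniform()
        c = confusion(pred, gt)
        assert abs(f1_score(c) - dice(c)) < 1e-12


# -- contours and BLE ---------------------------------------------------------

def test_contour_radii_circle():
    mask = _disk(64, (32, 32), 10)
    cr = contour_radii(mask)
    assert cr.n_rays == 24
    np.testing.assert_allclose(cr.radii, 10.0, atol=0.5)


def test_contour_radii_square_analytic():
    mask = np.zeros((64, 64), dtype=bool)
    mask[22:43, 22:43] = True          # square half-width 10 centered at 32
    cr = contour_radii(mask)
    for theta, r in zip(np.deg2rad(np.arange(24) * 15.0), cr.radii):
        c, s = abs(np.cos(theta)), abs(np.sin(theta))
        want = 10.0 / max(c, s)        # ray-box intersection distance
        assert abs(r - want) <= 0.75


def test_contour_radii_ellipse_four_rays():
    rr, cc = np.mgrid[0:96, 0:96]
    mask = ((rr - 48) / 10) ** 2 + ((cc - 48) / 20) ** 2 <= 1  # a=20 cols, b=10 rows
    cr = contour_radii(mask, n_rays=4)
    np.testing.assert_allclose(cr.radii, [20, 10, 20, 10], atol=0.75)


def test_contour_radii_rejects_empty_mask():
    with pytest.raises(ValueError):
        contour_radii(np.zeros((8, 8), dtype=bool))


def test_ble_identity_and_concentric_circles():
    big = contour_radii(_disk(64, (32, 32), 10), center=(32.0, 32.0))
    small = contour_radii(_disk(64, (32, 32), 8), center=(32.0, 32.0))
    assert ble(big, big) == 0.0
    assert abs(ble(small, big) - 2.0) < 0.3
    assert ble(small, big) == ble(big, small)  # symmetric


def test_ble_strict_formula_nan_on_overshoot():
    big = contour_radii(_disk(64, (32, 32), 10), center=(32.0, 32.0))
    small = contour_radii(_disk(64, (32, 32), 8), center=(32.0, 32.0))
    # prediction larger than ground truth: radicand negative
    assert np.isnan(ble(big, small, strict_formula=True))
    val = ble(small, big, strict_formula=True)
    assert np.isfinite(val) and val > 0


def test_ble_rejects_mismatched_ray_counts():
    a = contour_radii(_disk(64, (32, 32), 10), n_rays=24)
    b = contour_radii(_disk(64, (32, 32), 10), n_rays=12)
    with pytest.raises(ValueError):
        ble(a, b)


# -- CDR ----------------------------------------------------------------------

def test_cdr_from_extents():
    disc = np.zeros((200, 50), dtype=bool)
    disc[40:140] = True                # vertical extent 100
    cup = np.zeros((200, 50), dtype=bool)
    cup[70:110] = True                 # vertical extent 40
    assert cdr(disc, cup) == pytest.approx(0.4)


def test_cdr_identical_masks_is_one():
    disc = _disk(64, (32, 32), 12)
    assert cdr(disc, disc) == 1.0


def test_cdr_empty_cases():
    disc = _disk(64, (32, 32), 12)
    with pytest.warns(UserWarning):
        assert cdr(disc, np.zeros_like(disc)) == 0.0
    with pytest.raises(ValueError):
        cdr(np.zeros_like(disc), disc)


def test_cdr_matches_generator_cup_scale():
    s = make_sample(SceneParams(disc_axes=(30.0, 30.0), cup_scale=0.4,
                                cup_offset=(0.0, 0.0)))
    assert abs(cdr(s.disc_mask, s.cup_mask) - 0.4) <= 0.02


# -- aggregate report and invariances ----------------------------------------

def test_metrics_translation_invariant():
    base_disc = _disk(96, (40, 40), 14)
    base_cup = _disk(96, (40, 40), 7)
    pred_disc = _disk(96, (41, 40), 13)
    pred_cup = _disk(96, (40, 41), 6)
    r0 = evaluate_masks(pred_disc, pred_cup, base_disc, base_cup)
    shift = lambda m: np.roll(np.roll(m, 9, axis=0), -7, axis=1)
    r1 = evaluate_masks(shift(pred_disc), shift(pred_cup),
                        shift(base_disc), shift(base_cup))
    for key in ("f1", "dice"):
        assert r0.disc[key] == pytest.approx(r1.disc[key], abs=1e-9)
        assert r0.cup[key] == pytest.approx(r1.cup[key], abs=1e-9)
    # BLE is quantized by the 0.25-px ray marching; a single step on a single
    # ray (0.25/24) is the attainable translation tolerance
    for key in ("ble",):
        assert r0.disc[key] == pytest.approx(r1.disc[key], abs=0.25 / 24 + 1e-9)
        assert r0.cup[key] == pytest.approx(r1.cup[key], abs=0.25 / 24 + 1e-9)
    assert r0.cdr_pred == pytest.approx(r1.cdr_pred)


def test_evaluate_masks_report_fields():
    disc = _disk(64, (32, 32), 12)
    cup = _disk(64, (32, 32), 5)
    rep = evaluate_masks(disc, cup, disc, cup)
    flat = rep.flat()
    assert flat["disc_f1"] == flat["cup_f1"] == 1.0
    assert flat["disc_ble"] == 0.0
    assert rep.cdr_pred == rep.cdr_gt
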