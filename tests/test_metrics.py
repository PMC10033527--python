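"""Segmentation metrics, vertical-diameter/CDR extraction and screening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eards.exceptions import ShapeError
from eards.metrics import (
    CDRRecord,
    ConfusionCounts,
    balanced_accuracy,
    cdr,
    cdr_error,
    confusion_counts,
    dice_coefficient,
    jaccard,
    screen,
    sensitivity,
    specificity,
    structure_masks,
    vertical_diameter,
)


def loop_confusion(pred, ref):
    tp = fp = fn = tn = 0
    for y in range(pred.shape[0]):
        for x in range(pred.shape[1]):
            if pred[y, x] and ref[y, x]:
                tp += 1
            elif pred[y, x]:
                fp += 1
            elif ref[y, x]:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


class TestConfusion:
    def test_equal_masks(self, rng):
        m = rng.random((8, 8)) > 0.5
        c = confusion_counts(m, m)
        assert c.fp == c.fn == 0 and c.tp == m.sum()

    def test_complementary_masks(self, rng):
        m = rng.random((8, 8)) > 0.5
        c = confusion_counts(~m, m)
        assert c.tp == c.tn == 0

    def test_random_pair_matches_loop_oracle(self, rng):
        a, b = rng.random((16, 16)) > 0.4, rng.random((16, 16)) > 0.6
        c = confusion_counts(a, b)
        assert (c.tp, c.fp, c.fn, c.tn) == loop_confusion(a, b)
        assert c.total == 256

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))


class TestOverlapScores:
    def test_hand_worked_values(self):
        c = ConfusionCounts(tp=50, fp=10, fn=10, tn=930)
        assert dice_coefficient(c) == pytest.approx(100 / 120, abs=1e-9)
        assert dice_coefficient(c) == pytest.approx(0.83333, abs=1e-5)
        assert jaccard(c) == pytest.approx(50 / 70, abs=1e-9)
        assert jaccard(c) == pytest.approx(0.71429, abs=1e-5)
        assert sensitivity(c) == pytest.approx(50 / 60)
        assert specificity(c) == pytest.approx(930 / 940)
        assert balanced_accuracy(c) == pytest.approx(0.91135, abs=1e-5)

    def test_perfect_mask_scores_one(self):
        c = ConfusionCounts(tp=7, fp=0, fn=0, tn=9)
        assert dice_coefficient(c) == jaccard(c) == balanced_accuracy(c) == 1.0

    def test_dice_jaccard_identity_on_random_counts(self, rng):
        for _ in range(1000):
            c = ConfusionCounts(*(int(v) for v in rng.integers(0, 500, 4)))
            if c.tp + c.fp + c.fn == 0:
                continue
            d, j = dice_coefficient(c), jaccard(c)
            assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)

    def test_swapping_pred_ref_preserves_dice_jaccard(self, rng):
        a, b = rng.random((12, 12)) > 0.5, rng.random((12, 12)) > 0.5
        c1, c2 = confusion_counts(a, b), confusion_counts(b, a)
        assert (c1.fp, c1.fn) == (c2.fn, c2.fp)
        assert dice_coefficient(c1) == dice_coefficient(c2)
        assert jaccard(c1) == jaccard(c2)

    def test_degenerate_conventions(self):
        both_empty = ConfusionCounts(tp=0, fp=0, fn=0, tn=10)
        with pytest.warns(UserWarning):
            assert dice_coefficient(both_empty) == 1.0
        one_empty = ConfusionCounts(tp=0, fp=3, fn=0, tn=7)
        assert dice_coefficient(one_empty) == 0.0


class TestVerticalDiameter:
    def test_single_pixel(self):
        m = np.zeros((9, 9), bool); m[4, 4] = True
        assert vertical_diameter(m) == 1

    def test_filled_ellipse_rows_10_to_39(self):
        yy, xx = np.mgrid[0:64, 0:64]
        m = ((yy - 24.5) / 15.0) ** 2 + ((xx - 30) / 10.0) ** 2 <= 1
        occupied = np.flatnonzero(m.any(axis=1))
        assert occupied[0] == 10 and occupied[-1] == 39
        assert vertical_diameter(m) == 30

    def test_empty_mask_raises(self):
        with pytest.raises(ShapeError):
            vertical_diameter(np.zeros((4, 4), bool))

    def test_horizontal_flip_invariance_and_vertical_translation(self, rng):
        m = rng.random((20, 20)) > 0.7
        if not m.any():
            m[3, 3] = True
        assert vertical_diameter(m) == vertical_diameter(m[:, ::-1])
        assert vertical_diameter(np.roll(m, 0, axis=0)) == vertical_diameter(m)
        shifted = np.zeros_like(m)
        shifted[2:, :] = m[:-2, :]
        if m[-2:].any():          # content would fall off the edge
            return
        assert vertical_diameter(shifted) == vertical_diameter(m)


class TestCDR:
    def test_direct_ratio(self):
        disc = np.zeros((80, 40), bool); disc[10:70] = True      # vd 60
        cup = np.zeros((80, 40), bool); cup[20:50] = True        # vd 30
        assert cdr(cup, disc).value == pytest.approx(0.5)

    def test_cup_equals_disc(self):
        m = np.zeros((10, 10), bool); m[2:7] = True
        assert cdr(m, m).value == 1.0

    def test_empty_cup_warns_zero(self):
        disc = np.ones((5, 5), bool)
        with pytest.warns(UserWarning):
            assert cdr(np.zeros((5, 5), bool), disc).value == 0.0

    def test_empty_disc_raises(self):
        with pytest.raises(ShapeError):
            cdr(np.ones((5, 5), bool), np.zeros((5, 5), bool))

    def test_cdr_error_examples(self):
        recs = [CDRRecord(0.6, 0.65), CDRRecord(0.4, 0.35)]
        assert cdr_error(recs) == pytest.approx(0.05, abs=1e-12)
        assert cdr_error([CDRRecord(0.7, 0.5)]) == pytest.approx(0.2)
        assert cdr_error([CDRRecord(0.3, 0.3)] * 5) == 0.0
        with pytest.raises(ValueError):
            cdr_error([])


class TestScreening:
    def test_perfect_separation(self):
        rep = screen([0.9, 0.8, 0.2, 0.3], [1, 1, 0, 0])
        assert rep.auc == 1.0
        assert list(rep.decisions) == [True, True, False, False]

    def test_strict_threshold(self):
        rep = screen([0.51, 0.5], [1, 0], threshold=0.5)
        assert rep.decisions[0] and not rep.decisions[1]

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        rep = screen(scores, labels)
        assert rep.auc == pytest.approx(0.5, abs=0.03)

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.random(200)
        labels = (scores + rng.normal(0, 0.3, 200)) > 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        a1 = screen(scores, labels).auc
        a2 = screen(np.exp(3 * scores), labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_labels_raise(self):
        with pytest.raises(ValueError):
            screen([0.4, 0.6], [1, 1])


@settings(derandomize=True, max_examples=200)
@given(tp=st.integers(0, 10**6), fp=st.integers(0, 10**6),
       fn=st.integers(0, 10**6), tn=st.integers(0, 10**6))
def test_dice_jaccard_identity_property(tp, fp, fn, tn):
    """DC = 2*JAC/(1+JAC) for every confusion table with a non-empty union."""
    c = ConfusionCounts(tp, fp, fn, tn)
    if tp + fp + fn == 0:
        return
    d, j = dice_coefficient(c), jaccard(c)
    assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)
    assert 0.0 <= j <= d <= 1.0


@settings(derandomize=True, max_examples=100)
@given(rows=st.lists(st.integers(0, 63), min_size=1, max_size=20),
       shift=st.integers(0, 10))
def test_vertical_diameter_translation_equivariance(rows, shift):
    """Shifting the occupied rows down by s leaves the extent unchanged."""
    m = np.zeros((80, 5), bool)
    m[np.array(rows), 2] = True
    shifted = np.zeros_like(m)
    shifted[np.array(rows) + shift, 2] = True
    assert vertical_diameter(m) == vertical_diameter(shifted)
    assert vertical_diameter(m) == max(rows) - min(rows) + 1


def test_structure_masks_containment():
    label = np.array([[0, 1], [2, 2]])
    disc, cup = structure_masks(label)
    assert disc.sum() == 3 and cup.sum() == 2
    assert (cup <= disc).all()
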