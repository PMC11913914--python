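"""Unit and property tests for the evaluation primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from ennseg.metrics import (
    RocResult,
    binary_entropy,
    confusion_stats,
    dice,
    foreground_entropy,
    patient_dice,
    roc,
    youden_cutoff,
)


def _mask(*coords, shape=(8, 8)):
    m = np.zeros(shape, dtype=bool)
    for y, x in coords:
        m[y, x] = True
    return m


class TestDice:
    def test_identity_is_one(self):
        m = _mask((1, 1), (2, 3), (4, 4))
        assert dice(m, m) == 1.0

    def test_disjoint_masks_are_zero(self):
        # The gross-mislocalization failure picture: no overlap at all.
        assert dice(_mask((0, 0), (0, 1)), _mask((5, 5), (6, 6))) == 0.0

    def test_partial_overlap(self):
        p = _mask((0, 0), (0, 1), (0, 2), (0, 3))
        r = _mask((0, 2), (0, 3), (0, 4), (0, 5))
        assert dice(p, r) == pytest.approx(0.5)  # |P|=|R|=4, overlap 2

    def test_empty_conventions(self):
        empty = np.zeros((8, 8), dtype=bool)
        assert dice(empty, empty) == 1.0
        assert dice(empty, _mask((1, 1))) == 0.0
        assert dice(_mask((1, 1)), empty) == 0.0

    def test_symmetry_and_errors(self):
        rng = np.random.default_rng(0)
        a = rng.random((10, 10)) > 0.6
        b = rng.random((10, 10)) > 0.6
        assert dice(a, b) == dice(b, a)
        with pytest.raises(ValueError):
            dice(a, b[:5])
        with pytest.raises(ValueError):
            dice(a.astype(float) * 2.0, b)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_bounds(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((6, 6)) > 0.5
        b = rng.random((6, 6)) > 0.5
        assert 0.0 <= dice(a, b) <= 1.0


class TestBinaryEntropy:
    def test_closed_form_values(self):
        assert binary_entropy(0.5) == pytest.approx(1.0)
        assert binary_entropy(0.0) == 0.0
        assert binary_entropy(1.0) == 0.0
        assert binary_entropy(0.25) == pytest.approx(0.8112781244591328)

    def test_vectorized_and_symmetric(self):
        p = np.linspace(0, 1, 11)
        h = binary_entropy(p)
        assert np.allclose(h, h[::-1])
        assert h.max() == pytest.approx(1.0)

    def test_range_check(self):
        with pytest.raises(ValueError):
            binary_entropy(1.5)


class TestForegroundEntropy:
    def test_certain_foreground_is_zero(self):
        prob = np.zeros((5, 5))
        prob[1:3, 1:3] = 1.0
        e, empty = foreground_entropy(prob)
        assert e == 0.0 and not empty

    def test_mean_of_h_values(self):
        prob = np.zeros((4, 4))
        prob[0, 0] = 1.0
        prob[0, 1] = 0.5
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, :2] = True
        e, _ = foreground_entropy(prob, mask)
        assert e == pytest.approx(0.5)  # mean of H(1)=0 and H(0.5)=1

    def test_constant_half_inside_foreground(self):
        prob = np.full((6, 6), 0.5)
        mask = np.ones((6, 6), dtype=bool)
        e, _ = foreground_entropy(prob, mask)
        assert e == pytest.approx(1.0)

    def test_empty_foreground_convention(self):
        e, empty = foreground_entropy(np.zeros((5, 5)))
        assert e == 1.0 and empty

    def test_binary_fused_map_has_zero_entropy(self):
        rng = np.random.default_rng(1)
        prob = (rng.random((12, 12)) > 0.7).astype(float)
        if prob.any():
            e, _ = foreground_entropy(prob)
            assert e == 0.0


def _auc_bruteforce(scores, labels, low_is_positive=False):
    s = np.asarray(scores, dtype=float)
    if low_is_positive:
        s = -s
    pos = s[np.asarray(labels, dtype=bool)]
    neg = s[~np.asarray(labels, dtype=bool)]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _youden_bruteforce(result: RocResult):
    best = None
    for i in range(len(result.thresholds)):
        j = result.sensitivity[i] + result.specificity[i] - 1.0
        key = (j, result.sensitivity[i], -result.thresholds[i])
        if best is None or key > best[0]:
            best = (key, result.thresholds[i])
    return best[1]


class TestRoc:
    def test_perfect_separation(self):
        r = roc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0
        cutoff, sens, spec = youden_cutoff(r)
        assert sens == 1.0 and spec == 1.0
        assert 0.2 <= cutoff <= 0.8

    def test_worked_example(self):
        # Concordant pairs: (0.35,0.1), (0.8,0.1), (0.8,0.4); discordant: (0.35,0.4).
        r = roc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert r.auc == pytest.approx(0.75)

    def test_random_labels_auc_near_half(self):
        rng = np.random.default_rng(12)
        scores = rng.random(1000)
        labels = rng.integers(0, 2, 1000)
        assert roc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc([0.1, 0.2], [1, 1])

    def test_low_is_positive_polarity(self):
        # Low entropy predicts success: perfectly separating scores.
        r = roc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0], polarity="low_is_positive")
        assert r.auc == 1.0
        cutoff, sens, spec = youden_cutoff(r)
        assert sens == 1.0 and spec == 1.0
        assert 0.2 < cutoff <= 0.8

    @pytest.mark.parametrize("polarity", ["high_is_positive", "low_is_positive"])
    def test_auc_matches_concordance_and_sklearn(self, polarity):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(4, 60))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            r = roc(scores, labels, polarity=polarity)
            brute = _auc_bruteforce(scores, labels, polarity == "low_is_positive")
            assert r.auc == pytest.approx(brute, abs=1e-12)
            oriented = -scores if polarity == "low_is_positive" else scores
            assert r.auc == pytest.approx(roc_auc_score(labels, oriented), abs=1e-12)

    def test_youden_matches_exhaustive_search(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = int(rng.integers(5, 40))
            scores = np.round(rng.random(n), 1)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            r = roc(scores, labels, polarity="low_is_positive")
            cutoff, _, _ = youden_cutoff(r)
            assert cutoff == _youden_bruteforce(r)
            j = r.youden_index()
            assert np.all(j <= j.max() + 1e-12)


class TestConfusionStats:
    def test_identity_and_inversion(self):
        truth = [1, 0, 1, 0, 1]
        assert confusion_stats(truth, truth) == (1.0, 1.0, 1.0)
        inverted = [1 - t for t in truth]
        assert confusion_stats(inverted, truth) == (0.0, 0.0, 0.0)

    def test_worked_example(self):
        # TP=3, FN=1, TN=4, FP=2.
        truth = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        pred = [1, 1, 1, 0, 1, 1, 0, 0, 0, 0]
        sens, spec, acc = confusion_stats(pred, truth)
        assert sens == pytest.approx(0.75)
        assert spec == pytest.approx(2 / 3)
        assert acc == pytest.approx(0.7)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_stats([1, 0], [1])


class TestPatientDice:
    def test_single_slice_equals_slice_dice(self):
        p = _mask((1, 1), (1, 2))
        r = _mask((1, 2), (1, 3))
        assert patient_dice([(p, r)]) == dice(p, r)

    def test_pooled_equal_areas(self):
        # Two slices, dice 1 and 0, equal areas, |P| = |R| on both -> 0.5.
        a = _mask((0, 0), (0, 1))
        b = _mask((5, 5), (5, 6))
        c = _mask((2, 2), (2, 3))
        assert patient_dice([(a, a), (b, c)]) == pytest.approx(0.5)

    def test_pooled_differs_from_mean_when_areas_differ(self):
        big_p = np.zeros((8, 8), dtype=bool)
        big_p[:4, :4] = True  # 16 voxels, matches reference exactly
        small_p = _mask((7, 7))  # 1 voxel, disjoint from its reference
        small_r = _mask((0, 7))
        pooled = patient_dice([(big_p, big_p), (small_p, small_r)])
        per_slice_mean = (dice(big_p, big_p) + dice(small_p, small_r)) / 2
        assert pooled == pytest.approx(32 / 34)
        assert pooled != pytest.approx(per_slice_mean)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            patient_dice([])
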