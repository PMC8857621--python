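"""Accuracy, IoU, CVI, repeatability R, ICC and Bland-Altman agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from choroseg.core import Category, LabelMap, ShapeError
from choroseg.metrics import (
    PairedSeries,
    accuracy,
    bland_altman,
    confusion,
    cvi,
    evaluate,
    icc,
    iou,
    mean_iou,
    repeatability_R,
)

I, L, S = Category.INTERSTITIAL, Category.LUMEN, Category.SCLERA


def lm(rows):
    return LabelMap(np.array(rows, dtype=np.uint8))


class TestConfusionAndAccuracy:
    def test_perfect_prediction(self, rng):
        m = LabelMap(rng.integers(0, 3, size=(20, 20), dtype=np.uint8))
        counts = confusion(m, m)
        for c in Category:
            assert counts.fp(c) == 0 and counts.fn(c) == 0
        assert accuracy(counts) == 1.0

    def test_two_by_two_hand_example(self):
        truth = lm([[L, L], [I, I]])
        pred = lm([[L, I], [I, I]])
        counts = confusion(pred, truth)
        assert counts.tp(L) == 1 and counts.fn(L) == 1 and counts.fp(L) == 0
        assert accuracy(counts, L) == 0.5
        assert accuracy(counts) == 0.75

    def test_matches_naive_pixel_loop(self, rng):
        truth = rng.integers(0, 3, size=(50, 50), dtype=np.uint8)
        pred = rng.integers(0, 3, size=(50, 50), dtype=np.uint8)
        counts = confusion(pred, truth)
        for c in Category:
            tp = fp = fn = 0
            for i in range(50):
                for j in range(50):
                    if truth[i, j] == c and pred[i, j] == c:
                        tp += 1
                    elif truth[i, j] == c:
                        fn += 1
                    elif pred[i, j] == c:
                        fp += 1
            assert (counts.tp(c), counts.fp(c), counts.fn(c)) == (tp, fp, fn)

    def test_absent_class_is_missing_not_zero(self):
        counts = confusion(lm([[I, I]]), lm([[I, I]]))
        assert np.isnan(accuracy(counts, S))
        assert np.isnan(iou(counts, S))

    def test_total_accuracy_is_count_weighted_combination(self, rng):
        truth = rng.integers(0, 3, size=(30, 30), dtype=np.uint8)
        pred = rng.integers(0, 3, size=(30, 30), dtype=np.uint8)
        counts = confusion(pred, truth)
        weighted = sum(
            accuracy(counts, c) * (counts.tp(c) + counts.fn(c)) for c in Category
        ) / counts.n_pixels
        assert accuracy(counts) == pytest.approx(weighted)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            confusion(lm([[I]]), lm([[I, I]]))


class TestIoU:
    def test_formula_on_small_counts(self):
        truth = lm([[L, L], [I, S]])
        pred = lm([[L, I], [L, S]])
        counts = confusion(pred, truth)
        # class L: TP=1, FP=1, FN=1
        assert iou(counts, L) == pytest.approx(1 / 3)

    def test_iou_never_exceeds_class_accuracy(self, rng):
        for _ in range(100):
            truth = rng.integers(0, 3, size=(12, 12), dtype=np.uint8)
            pred = rng.integers(0, 3, size=(12, 12), dtype=np.uint8)
            counts = confusion(pred, truth)
            for c in Category:
                a, j = accuracy(counts, c), iou(counts, c)
                if not (np.isnan(a) or np.isnan(j)):
                    assert j <= a + 1e-12

    def test_mean_iou_skips_missing_classes(self):
        counts = confusion(lm([[I, L]]), lm([[I, L]]))
        assert mean_iou(counts) == 1.0


class TestCVI:
    def test_all_lumen_is_100(self):
        assert cvi(lm([[L, L], [L, L]])) == 100.0

    def test_sclera_excluded(self, rng):
        choroid = np.concatenate([np.full(60, L), np.full(40, I)])
        for n_sclera in (0, 37, 500):
            cats = np.concatenate([choroid, np.full(n_sclera, S)])
            rng.shuffle(cats)
            assert cvi(LabelMap(cats.reshape(1, -1).astype(np.uint8))) == 60.0

    def test_no_choroid_is_missing(self):
        assert np.isnan(cvi(lm([[S, S]])))

    def test_phantom_truth_matches_analytic_ellipse_areas(self):
        # low density keeps vessels disjoint, so the summed pi*a*b areas
        # should match the rasterized truth within rasterization error
        from choroseg.phantom import PhantomSpec, generate_phantom

        spec = PhantomSpec(seed=3, vessel_density=0.05, speckle_level=0.0)
        _, b, truth = generate_phantom(spec)
        thickness = b.ocb - b.icb
        band = int(
            (np.arange(truth.labels.shape[0])[:, None] < thickness[None, :]).sum()
        )
        analytic = 100 * sum(v.area for v in truth.vessels) / band
        assert cvi(truth.labels) == pytest.approx(analytic, abs=1.0)


class TestRepeatability:
    def test_identical_maps_are_zero(self, rng):
        m = LabelMap(rng.integers(0, 3, size=(10, 10), dtype=np.uint8))
        for c in Category:
            assert repeatability_R(m, m, c) == 0.0

    def test_formula(self):
        a = np.zeros((100, 100), dtype=np.uint8)
        b = a.copy()
        b.ravel()[:150] = L
        assert repeatability_R(LabelMap(a), LabelMap(b), L) == pytest.approx(1.5)

    @settings(derandomize=True, max_examples=20)
    @given(
        arrays(np.uint8, (6, 8), elements=st.integers(0, 2)),
        arrays(np.uint8, (6, 8), elements=st.integers(0, 2)),
    )
    def test_pseudometric(self, a, b):
        for c in Category:
            r_ab = repeatability_R(a, b, c)
            assert r_ab >= 0
            assert r_ab == repeatability_R(b, a, c)


class TestICC:
    def test_identical_series(self):
        v = np.array([55.0, 60.0, 62.0, 58.0])
        assert icc(PairedSeries(v, v)) == 1.0

    def test_independent_pairs_near_zero(self, rng):
        a = rng.normal(60, 3, size=1000)
        b = rng.normal(60, 3, size=1000)
        assert abs(icc(PairedSeries(a, b))) <= 0.1

    def test_recovers_variance_ratio(self, rng):
        # between-subject SD 3, within SD 1 -> ICC = 9 / (9 + 1)
        subject = rng.normal(60, 3, size=400)
        pairs = PairedSeries(
            subject + rng.normal(0, 1, size=400),
            subject + rng.normal(0, 1, size=400),
        )
        assert icc(pairs) == pytest.approx(0.9, abs=0.05)

    def test_zero_variance_is_missing(self):
        v = np.full(5, 60.0)
        assert np.isnan(icc(PairedSeries(v, v)))

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            icc(PairedSeries([1.0, 2.0], [1.0, 2.0]))


class TestBlandAltman:
    def test_identical_series(self):
        v = np.array([1.0, 2.0, 3.0])
        assert bland_altman(PairedSeries(v, v)) == (0.0, 0.0)

    def test_three_pair_example(self):
        pairs = PairedSeries([10.0, 20.0, 30.0], [12.0, 18.0, 31.0])
        mean_diff, halfwidth = bland_altman(pairs)
        d = np.array([-2.0, 2.0, -1.0])
        assert mean_diff == pytest.approx(d.mean())
        assert halfwidth == pytest.approx(1.96 * d.std(ddof=1))

    def test_recovers_simulation_parameters(self, rng):
        base = rng.normal(60, 3, size=5000)
        diffs = rng.normal(0.1, 1.2, size=5000)
        mean_diff, halfwidth = bland_altman(PairedSeries(base + diffs, base))
        assert mean_diff == pytest.approx(0.1, abs=0.05)
        assert halfwidth == pytest.approx(1.96 * 1.2, abs=0.1)


class TestEvaluateReport:
    def test_report_fields(self, rng):
        truth = LabelMap(rng.integers(0, 3, size=(20, 20), dtype=np.uint8))
        pairs = PairedSeries(
            rng.normal(60, 3, size=10), rng.normal(60, 3, size=10)
        )
        report = evaluate(truth, truth, repeat_pred=truth, cvi_pairs=pairs)
        assert report.total_accuracy == 1.0
        assert set(report.per_class_accuracy) == {"interstitial", "lumen", "sclera"}
        assert all(v == 0.0 for v in report.repeatability_R.values())
        assert 0 <= report.cvi_percent <= 100
        d = report.to_dict()
        assert {"icc", "mean_difference", "loa_halfwidth"} <= set(d)
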