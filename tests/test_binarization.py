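"""Niblack thresholding, lumen/interstitial classification, sclera masking,
and the CVI-versus-window-size sweep."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from choroseg.binarization import (
    NiblackParams,
    binarize,
    classify_choroid,
    mask_sclera,
    niblack_threshold_map,
    select_window,
    window_sweep_cvi,
)
from choroseg.core import Category, LabelMap, ShapeError
from choroseg.flattening import FlattenedChoroid, flatten_bscan
from choroseg.metrics import cvi
from choroseg.phantom import PhantomSpec, generate_phantom


def naive_niblack(image, window, k):
    """Reference implementation: explicit window loop on padded data."""
    image = np.asarray(image, dtype=np.float64)
    lo = window // 2
    hi = window - lo - 1
    padded = np.pad(image, ((lo, hi), (lo, hi)), mode="symmetric")
    out = np.empty_like(image)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            win = padded[i : i + window, j : j + window]
            out[i, j] = win.mean() + k * win.std()  # population SD
    return out


class TestThresholdMap:
    def test_constant_image_threshold_equals_value(self):
        t = niblack_threshold_map(np.full((9, 9), 137.0), window=5, k=-0.05)
        assert np.allclose(t, 137.0)

    def test_k_zero_gives_local_mean(self, rng):
        img = rng.integers(0, 256, size=(12, 15)).astype(float)
        t = niblack_threshold_map(img, window=5, k=0.0)
        assert np.allclose(t, naive_niblack(img, 5, 0.0), atol=1e-9)

    def test_single_outlier_center_value(self):
        # 3x3 window around the center: eight 10s and one 100
        # mean 20, population sigma = sqrt(800), T = 20 - 0.05*sqrt(800)
        img = np.full((5, 5), 10.0)
        img[2, 2] = 100.0
        t = niblack_threshold_map(img, window=3, k=-0.05)
        assert t[2, 2] == pytest.approx(20.0 - 0.05 * np.sqrt(800.0), abs=1e-9)
        assert t[2, 2] == pytest.approx(18.585786437626904, abs=1e-9)

    @pytest.mark.parametrize("window", [3, 4, 5, 8, 9, 15])
    @pytest.mark.parametrize("k", [-0.05, 0.0, 0.2])
    def test_matches_naive_loop(self, rng, window, k):
        img = rng.integers(0, 256, size=(20, 26)).astype(float)
        t = niblack_threshold_map(img, window=window, k=k)
        assert np.abs(t - naive_niblack(img, window, k)).max() <= 1e-9

    def test_interior_agrees_with_skimage(self, rng):
        # independent implementation; borders differ (other padding mode)
        from skimage.filters import threshold_niblack

        img = rng.integers(0, 256, size=(40, 50)).astype(float)
        w = 9
        ours = niblack_threshold_map(img, window=w, k=-0.05)
        # skimage parameterizes the threshold as m - k*sigma, so its k flips sign
        ref = threshold_niblack(img, window_size=w, k=0.05)
        interior = (slice(w, -w), slice(w, -w))
        assert np.allclose(ours[interior], ref[interior], atol=1e-7)

    def test_window_bounds(self):
        with pytest.raises(ValueError):
            NiblackParams(window=2)
        with pytest.raises(ValueError):
            niblack_threshold_map(np.zeros((10, 10)), window=21)


class TestClassify:
    def test_tie_goes_to_interstitial(self, rng):
        img = rng.integers(0, 256, size=(8, 8)).astype(float)
        labels = classify_choroid(img, img)
        assert (labels.categories == Category.INTERSTITIAL).all()

    def test_strictly_below_is_lumen(self):
        img = np.array([[10.0, 100.0]])
        t = np.array([[18.0, 18.0]])
        labels = classify_choroid(img, t)
        assert labels.categories[0, 0] == Category.LUMEN
        assert labels.categories[0, 1] == Category.INTERSTITIAL

    def test_per_pixel_against_threshold_map(self, rng):
        img = rng.integers(0, 256, size=(16, 20)).astype(float)
        t = niblack_threshold_map(img, window=5, k=-0.05)
        labels = classify_choroid(img, t)
        assert np.array_equal(
            labels.categories == Category.LUMEN, img < t
        )

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            classify_choroid(np.zeros((4, 4)), np.zeros((4, 5)))

    def test_monotone_in_k(self, rng):
        # lowering k lowers the threshold, so lumen count cannot grow
        img = rng.integers(0, 256, size=(30, 30)).astype(float)
        counts = []
        for k in (0.2, 0.0, -0.05, -0.3):
            labels = classify_choroid(img, niblack_threshold_map(img, window=7, k=k))
            counts.append(int((labels.categories == Category.LUMEN).sum()))
        assert counts == sorted(counts, reverse=True)

    def test_vessel_interiors_predominantly_lumen(self, phantom_sample):
        scan, b, truth = phantom_sample
        flat = flatten_bscan(scan, b, truth.labels.shape[0])
        labels = binarize(flat, window=22)  # ~2x mean vessel diameter
        vessel = truth.labels.categories == Category.LUMEN
        hit = (labels.categories[vessel] == Category.LUMEN).mean()
        assert hit >= 0.90


class TestMaskSclera:
    def test_empty_and_total_mask(self):
        labels = LabelMap(np.zeros((6, 4), dtype=np.uint8))
        untouched = mask_sclera(labels, np.full(4, 6))
        assert (untouched.categories == Category.INTERSTITIAL).all()
        full = mask_sclera(labels, np.zeros(4, dtype=int))
        assert (full.categories == Category.SCLERA).all()

    def test_sclera_count_matches_columnwise_sum(self, phantom_sample):
        _, _, truth = phantom_sample
        rows = truth.labels.shape[0]
        expected = int(np.sum(rows - truth.ocb_flat))
        n_sclera = int((truth.labels.categories == Category.SCLERA).sum())
        assert n_sclera == expected

    def test_commutes_with_classification(self, rng):
        img = rng.integers(0, 256, size=(20, 12)).astype(float)
        ocb = rng.integers(5, 18, size=12)
        t = niblack_threshold_map(img, window=5, k=-0.05)
        mask_first = classify_choroid(img, t, ocb_flat=ocb)
        mask_after = mask_sclera(classify_choroid(img, t), ocb)
        assert np.array_equal(mask_first.categories, mask_after.categories)


class TestWindowSweep:
    def test_sweep_range_has_56_entries(self, phantom_sample):
        scan, b, truth = phantom_sample
        flat = flatten_bscan(scan, b, truth.labels.shape[0])
        sweep = window_sweep_cvi(flat)
        assert len(sweep) == 56
        assert [w for w, _ in sweep] == list(range(20, 76))

    def test_sweep_deterministic(self, phantom_sample):
        scan, b, truth = phantom_sample
        flat = flatten_bscan(scan, b, truth.labels.shape[0])
        a = window_sweep_cvi(flat, [31, 31])
        assert a[0][1] == a[1][1]

    def test_sweep_cvi_recovers_programmed_fraction(self, phantom_sample):
        scan, b, truth = phantom_sample
        flat = flatten_bscan(scan, b, truth.labels.shape[0])
        [(_, value)] = window_sweep_cvi(flat, [22])
        assert value == pytest.approx(100 * truth.luminal_fraction, abs=3.0)

    def test_empty_windows_rejected(self, phantom_sample):
        scan, b, truth = phantom_sample
        flat = flatten_bscan(scan, b, truth.labels.shape[0])
        with pytest.raises(ValueError):
            window_sweep_cvi(flat, [])


class TestSelectWindow:
    def test_nearest_to_truth(self):
        assert select_window([(20, 50.0), (30, 60.0), (40, 61.0)], truth=60.0) == 30

    def test_plateau_start_without_truth(self):
        sweep = [(20, 40.0), (30, 50.0), (40, 55.0), (50, 55.0), (60, 55.0)]
        assert select_window(sweep) == 40

    def test_empty_sweep(self):
        with pytest.raises(ValueError):
            select_window([])

    def test_selected_window_tracks_vessel_size(self):
        # larger programmed vessels need larger analysis windows
        sizes, selected = [], []
        for s in range(20):
            r = 2.0 + (s % 10) * 0.8
            spec = PhantomSpec(seed=s, vessel_radius_range=(max(r - 1.5, 1.0), r + 1.5))
            scan, b, truth = generate_phantom(spec)
            flat = flatten_bscan(scan, b, truth.labels.shape[0])
            sweep = window_sweep_cvi(flat, range(20, 76, 5))
            selected.append(select_window(sweep, truth=100 * truth.luminal_fraction))
            sizes.append(r)
        assert spearmanr(sizes, selected).statistic > 0.5
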