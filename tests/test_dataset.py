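"""Network-grid resampling, ground-truth painting, tiling, subject-grouped
splits, and the dataset proportion summary."""

import numpy as np
import pytest

from choroseg.core import CATEGORY_COLORS, Category, LabelMap, ShapeError
from choroseg.dataset import (
    GRID_COLS,
    GRID_ROWS,
    TILE_OFFSETS,
    TILE_SIZE,
    build_ground_truth,
    reassemble,
    resample_to_grid,
    split_by_subject,
    summarize_proportions,
    tile_image,
)
from choroseg.flattening import FlattenedChoroid, flatten_bscan
from choroseg.metrics import cvi


@pytest.fixture(scope="module")
def grid_flat(phantom_sample):
    scan, b, truth = phantom_sample
    return resample_to_grid(flatten_bscan(scan, b, truth.labels.shape[0]))


class TestTiling:
    def test_four_tiles_at_fixed_offsets(self, rng):
        img = rng.integers(0, 256, size=(GRID_ROWS, GRID_COLS), dtype=np.uint8)
        ts = tile_image(img)
        assert len(ts.tiles) == 4
        assert ts.offsets == (0, 224, 448, 672)
        assert all(t.shape == (TILE_SIZE, TILE_SIZE) for t in ts.tiles)

    def test_reassembly_is_byte_exact(self, rng):
        img = rng.integers(0, 256, size=(GRID_ROWS, GRID_COLS, 3), dtype=np.uint8)
        assert np.array_equal(reassemble(tile_image(img)), img)

    def test_offset_arithmetic(self, rng):
        img = rng.integers(0, 256, size=(GRID_ROWS, GRID_COLS), dtype=np.uint8)
        ts = tile_image(img)
        assert ts.tiles[2][13, 5] == img[13, 448 + 5]
        assert ts.tiles[3][0, 10] == img[0, 672 + 10]

    def test_wrong_shape_rejected(self):
        with pytest.raises(ShapeError):
            tile_image(np.zeros((224, 895), dtype=np.uint8))


class TestResampling:
    def test_grid_geometry(self, grid_flat):
        assert grid_flat.pixels.shape == (GRID_ROWS, GRID_COLS)
        assert grid_flat.ocb_flat.shape == (GRID_COLS,)
        assert grid_flat.ocb_flat.max() <= GRID_ROWS

    def test_identity_when_already_on_grid(self, rng):
        flat = FlattenedChoroid(
            pixels=rng.integers(0, 256, size=(GRID_ROWS, GRID_COLS), dtype=np.uint8),
            shift=np.zeros(GRID_COLS, dtype=int),
            ocb_flat=np.full(GRID_COLS, 100),
        )
        assert resample_to_grid(flat) is flat


class TestGroundTruth:
    def test_sclera_painted_in_input(self, grid_flat):
        image, labels = build_ground_truth(grid_flat)
        sclera = labels.categories == Category.SCLERA
        assert sclera.any()
        assert (image[sclera] == CATEGORY_COLORS[Category.SCLERA]).all()
        choroid = ~sclera
        assert (image[choroid][:, 0] == image[choroid][:, 1]).all()
        assert (image[choroid][:, 1] == image[choroid][:, 2]).all()

    def test_unpainted_variant_is_plain_grayscale(self, grid_flat):
        image, _ = build_ground_truth(grid_flat, paint_sclera=False)
        assert (image[:, :, 0] == image[:, :, 1]).all()
        assert (image[:, :, 1] == image[:, :, 2]).all()

    def test_no_sclera_column_stays_grayscale(self):
        rng = np.random.default_rng(0)
        flat = FlattenedChoroid(
            pixels=rng.integers(0, 256, size=(GRID_ROWS, GRID_COLS), dtype=np.uint8),
            shift=np.zeros(GRID_COLS, dtype=int),
            ocb_flat=np.full(GRID_COLS, GRID_ROWS),
        )
        image, labels = build_ground_truth(flat)
        assert not (labels.categories == Category.SCLERA).any()
        assert (image[:, :, 0] == flat.pixels).all()

    def test_label_cvi_matches_binarization_module(self, grid_flat):
        from choroseg.binarization import binarize

        _, labels = build_ground_truth(grid_flat, window=31)
        reference = binarize(grid_flat, window=31)
        assert cvi(labels) == cvi(reference)

    def test_requires_grid_geometry(self, rng):
        flat = FlattenedChoroid(
            pixels=rng.integers(0, 256, size=(59, 896), dtype=np.uint8),
            shift=np.zeros(896, dtype=int),
            ocb_flat=np.full(896, 44),
        )
        with pytest.raises(ShapeError):
            build_ground_truth(flat)


class TestSplit:
    def test_ten_subjects_give_6_2_2(self):
        subjects = [f"S{i}" for i in range(10)]
        split = split_by_subject(subjects, seed=3)
        sizes = {p: len(split.subjects(p)) for p in ("train", "validation", "test")}
        assert sizes == {"train": 6, "validation": 2, "test": 2}

    def test_deterministic_given_seed(self):
        subjects = [f"S{i}" for i in range(25)]
        a = split_by_subject(subjects, seed=9)
        b = split_by_subject(subjects, seed=9)
        assert a.assignment == b.assignment

    def test_every_subject_in_exactly_one_partition(self):
        subjects = [f"S{i}" for i in range(17)]
        split = split_by_subject(subjects, seed=1)
        assert sorted(split.assignment) == sorted(subjects)
        total = sum(len(split.subjects(p)) for p in ("train", "validation", "test"))
        assert total == 17

    def test_group_integrity_on_corpus(self):
        from choroseg.phantom import generate_corpus

        _, manifest = generate_corpus(8, visits=2, seed=6)
        split = split_by_subject(manifest["subject"].tolist(), seed=0)
        for subject, group in manifest.groupby("subject"):
            parts = {split.partition_of(subject)}
            assert len(parts) == 1

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            split_by_subject(["a", "b"])


class TestSummary:
    def test_half_lumen_image(self):
        cats = np.zeros((10, 10), dtype=np.uint8)
        cats[:5] = Category.LUMEN
        df = summarize_proportions({"train": [LabelMap(cats)]})
        row = df.loc["train"]
        assert row["lumen_pct_mean"] == 50.0
        assert row["lumen_pct_sd"] == 0.0
        assert row["cvi_pct_mean"] == 50.0

    def test_all_sclera_cvi_missing(self):
        cats = np.full((4, 4), int(Category.SCLERA), dtype=np.uint8)
        df = summarize_proportions({"test": [LabelMap(cats)]})
        row = df.loc["test"]
        assert row["sclera_pct_mean"] == 100.0
        assert np.isnan(row["cvi_pct_mean"])

    def test_phantom_corpus_partition_means(self):
        from choroseg.pipeline import phantom_ground_truth_corpus

        _, scans = phantom_ground_truth_corpus(6, seed=50)
        df = summarize_proportions({"train": [lab for _, lab in scans]})
        assert df.loc["train", "cvi_pct_mean"] == pytest.approx(60.0, abs=3.0)
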