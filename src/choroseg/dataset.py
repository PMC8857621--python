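"""Assembly of network-ready ground truth from flattened choroid scans.

The segmentation networks consume 224x224x3 tiles.  A flattened scan is
resampled to the 224x896 network grid (bilinear for intensities, nearest
neighbour for anything categorical), the Niblack labels are computed, the
scleral region is painted into the input with the (127, 0, 0) mask color,
and the image/label pair is split into four non-overlapping 224x224 tiles
at column offsets 0, 224, 448 and 672.  Evaluation happens on reassembled
224x896 images, not on individual tiles, so tiling never biases metrics.

Subjects are allocated whole to the train/validation/test partitions
(60/20/20 by default): every scan of a subject — all visits, repeats and
orientations — lands in exactly one partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize

from .binarization import DEFAULT_K, FIXED_WINDOW, binarize
from .core import CATEGORY_COLORS, Category, LabelMap, ShapeError, as_categories
from .flattening import FlattenedChoroid
from .metrics import cvi

#: Geometry of the network grid and its tiles.
GRID_ROWS = 224
GRID_COLS = 896
TILE_SIZE = 224
TILE_OFFSETS = (0, 224, 448, 672)

_SCLERA_COLOR = np.array(CATEGORY_COLORS[Category.SCLERA], dtype=np.uint8)


def resample_to_grid(flat: FlattenedChoroid) -> FlattenedChoroid:
    """Resample a flattened scan onto the 224x896 network grid.

    Intensities are interpolated bilinearly; the flattened OCB trace is
    scaled to the new geometry (rows by the height ratio, columns by
    nearest-neighbour lookup).  The per-column shift is resampled the same
    way so provenance survives, though it plays no further role on the grid.
    """
    if flat.pixels.shape == (GRID_ROWS, GRID_COLS):
        return flat
    row_scale = GRID_ROWS / flat.crop_height
    pixels = resize(
        flat.pixels.astype(np.float64),
        (GRID_ROWS, GRID_COLS),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    src_cols = np.clip(
        np.rint(np.arange(GRID_COLS) * flat.n_cols / GRID_COLS).astype(np.int64),
        0,
        flat.n_cols - 1,
    )
    ocb = np.clip(np.rint(flat.ocb_flat[src_cols] * row_scale), 0, GRID_ROWS).astype(
        np.int64
    )
    return FlattenedChoroid(
        pixels=np.clip(np.rint(pixels), 0, 255).astype(np.uint8),
        shift=flat.shift[src_cols],
        ocb_flat=ocb,
    )


def resample_labels_to_grid(labels: LabelMap) -> LabelMap:
    """Nearest-neighbour resampling of a label map onto the network grid."""
    cats = as_categories(labels)
    if cats.shape == (GRID_ROWS, GRID_COLS):
        return LabelMap(cats.copy())
    out = resize(
        cats, (GRID_ROWS, GRID_COLS), order=0, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return LabelMap(out.astype(np.uint8))


def build_ground_truth(
    flat: FlattenedChoroid,
    window: int = FIXED_WINDOW,
    k: float = DEFAULT_K,
    paint_sclera: bool = True,
) -> tuple[np.ndarray, LabelMap]:
    """Network input and label map for one grid-resolution flattened scan.

    The input is the grayscale replicated to three channels with scleral
    pixels painted (127, 0, 0) — the same mask color as in the labels —
    which turns sclera detection into a highlighted-region task.  Labels
    come from Niblack classification plus sclera masking.  With
    ``paint_sclera=False`` the input stays plain grayscale (labels are
    unchanged), so the effect of the mask on training can be measured.
    """
    if flat.pixels.shape != (GRID_ROWS, GRID_COLS):
        raise ShapeError(
            f"expected a {GRID_ROWS}x{GRID_COLS} grid scan; resample first"
        )
    labels = binarize(flat, window=window, k=k)
    image = np.repeat(flat.pixels[:, :, None], 3, axis=2)
    if paint_sclera:
        sclera = as_categories(labels) == Category.SCLERA
        image[sclera] = _SCLERA_COLOR
    return image, labels


@dataclass
class TileSet:
    """Four non-overlapping 224x224 tiles of one 224x896 parent image."""

    tiles: list[np.ndarray]
    offsets: tuple[int, ...] = TILE_OFFSETS
    parent_id: str = ""

    def __post_init__(self) -> None:
        if len(self.tiles) != len(self.offsets):
            raise ShapeError("one offset per tile required")


def tile_image(image: np.ndarray, parent_id: str = "") -> TileSet:
    """Split a 224x896 image (grayscale, color or labels) into 4 tiles."""
    image = np.asarray(image)
    if image.shape[:2] != (GRID_ROWS, GRID_COLS):
        raise ShapeError(
            f"expected {GRID_ROWS}x{GRID_COLS} image, got {image.shape[:2]}"
        )
    tiles = [image[:, off : off + TILE_SIZE].copy() for off in TILE_OFFSETS]
    return TileSet(tiles=tiles, parent_id=parent_id)


def reassemble(tileset: TileSet) -> np.ndarray:
    """Concatenate the 4 tiles back into the 224x896 parent (byte-exact)."""
    order = np.argsort(tileset.offsets)
    return np.concatenate([tileset.tiles[i] for i in order], axis=1)


@dataclass
class SplitAssignment:
    """Subject-level partition assignment with its seed and target fractions."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def subjects(self, partition: str) -> list[str]:
        return sorted(s for s, p in self.assignment.items() if p == partition)

    def partition_of(self, subject: str) -> str:
        return self.assignment[subject]


def split_by_subject(
    subjects: Sequence[str],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Deterministic 60/20/20 split that keeps each subject in one partition.

    Partition sizes are the rounded fractions of the subject count,
    largest-remainder corrected so they sum exactly and every partition
    gets at least one subject.
    """
    subjects = list(dict.fromkeys(subjects))
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects to fill 3 partitions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(subjects)
    raw = np.array(fractions) * n
    counts = np.floor(raw).astype(int)
    counts = np.maximum(counts, 1)
    while counts.sum() > n:
        counts[int(np.argmax(counts))] -= 1
    rema = raw - np.floor(raw)
    while counts.sum() < n:
        i = int(np.argmax(rema))
        counts[i] += 1
        rema[i] = -1
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    names = ("train", "validation", "test")
    assignment: dict[str, str] = {}
    pos = 0
    for name, c in zip(names, counts):
        for idx in order[pos : pos + c]:
            assignment[subjects[idx]] = name
        pos += c
    return SplitAssignment(assignment=assignment, fractions=tuple(fractions), seed=seed)


def summarize_proportions(
    labelsets: Mapping[str, Iterable[LabelMap | np.ndarray]],
) -> pd.DataFrame:
    """Per-partition mean ± SD of category percentages and CVI.

    Category percentages are over all pixels of each image; CVI is over
    choroidal pixels only and is reported as missing (NaN) for images with
    no choroid, never as 0.
    """
    rows = []
    for partition, maps in labelsets.items():
        per_image = []
        for lm in maps:
            cats = as_categories(lm)
            binc = np.bincount(cats.ravel(), minlength=3)
            total = cats.size
            per_image.append(
                {
                    "interstitial_pct": 100.0 * binc[Category.INTERSTITIAL] / total,
                    "lumen_pct": 100.0 * binc[Category.LUMEN] / total,
                    "sclera_pct": 100.0 * binc[Category.SCLERA] / total,
                    "cvi_pct": cvi(cats),
                }
            )
        if not per_image:
            raise ValueError(f"partition {partition!r} is empty")
        df = pd.DataFrame(per_image)
        row: dict[str, float | str | int] = {
            "partition": partition,
            "n_images": len(per_image),
        }
        for col in df.columns:
            row[f"{col}_mean"] = float(df[col].mean())
            row[f"{col}_sd"] = float(df[col].std(ddof=1)) if len(df) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("partition")


__all__ = [
    "GRID_COLS",
    "GRID_ROWS",
    "SplitAssignment",
    "TILE_OFFSETS",
    "TILE_SIZE",
    "TileSet",
    "build_ground_truth",
    "reassemble",
    "resample_labels_to_grid",
    "resample_to_grid",
    "split_by_subject",
    "summarize_proportions",
    "tile_image",
]
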