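"""Convenience composition of the pipeline stages on phantom data.

These helpers wire phantom generation, flattening, grid resampling and
ground-truth construction together the way the full study pipeline does,
so experiments and scripts do not re-implement the plumbing.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .binarization import FIXED_WINDOW, DEFAULT_K
from .core import LabelMap
from .dataset import build_ground_truth, resample_to_grid, tile_image
from .flattening import compute_crop_height, flatten_bscan
from .phantom import PhantomSpec, generate_phantom


def phantom_ground_truth_corpus(
    n_scans: int,
    seed: int = 0,
    density: float = 0.60,
    window: int = FIXED_WINDOW,
    k: float = DEFAULT_K,
    paint_sclera: bool = True,
    base_spec: PhantomSpec | None = None,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], list[tuple[np.ndarray, LabelMap]]]:
    """Phantoms -> flatten -> network grid -> (input, label) ground truth.

    Returns ``(tile_pairs, scans)``: 4 tile pairs per scan for training,
    plus the full 224x896 input image and label map of each scan for
    whole-scan evaluation.  Scan ``i`` uses seed ``seed + i``; the crop
    height is shared across the corpus, as in a real dataset.
    """
    base = base_spec or PhantomSpec()
    samples = [
        generate_phantom(replace(base, vessel_density=density, seed=seed + i))
        for i in range(n_scans)
    ]
    crop_height = compute_crop_height([s.boundaries for s in samples])
    tile_pairs: list[tuple[np.ndarray, np.ndarray]] = []
    scans: list[tuple[np.ndarray, LabelMap]] = []
    for sample in samples:
        flat = resample_to_grid(
            flatten_bscan(sample.scan, sample.boundaries, crop_height)
        )
        image, labels = build_ground_truth(
            flat, window=window, k=k, paint_sclera=paint_sclera
        )
        for timg, tlab in zip(
            tile_image(image).tiles, tile_image(labels.categories).tiles
        ):
            tile_pairs.append((timg, tlab))
        scans.append((image, labels))
    return tile_pairs, scans


__all__ = ["phantom_ground_truth_corpus"]
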