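"""Curvature compensation ("flattening") of the choroid in OCT B-scans.

Local binarization operates on a rectangular region, but the posterior eye
is curved, so the choroid band wanders vertically across the scan.  Each
A-scan (column) is shifted up by its ICB row so the inner choroidal
boundary sits on row 0, then a fixed-height rectangle containing the whole
choroid plus a slab of sclera is cropped.  The crop height is a single
value for a whole dataset: the maximum choroidal thickness over every
column of every image, plus a scleral margin.  Shifts are whole pixels —
no resampling — so 8-bit intensities are preserved exactly and flattening
is a pure permutation of the in-range pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import BScan, ChoroidBoundaries, ShapeError

#: Default number of scleral rows retained below the deepest flattened OCB.
DEFAULT_SCLERAL_MARGIN = 15


@dataclass
class FlattenedChoroid:
    """A B-scan after per-column ICB alignment and fixed-height cropping.

    ``shift[c]`` is the number of rows column ``c`` was moved up (its
    original ICB row) and ``ocb_flat[c] = ocb[c] - icb[c]`` is the flattened
    OCB, i.e. the local choroidal thickness.
    """

    pixels: np.ndarray
    shift: np.ndarray
    ocb_flat: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.shift = np.asarray(self.shift, dtype=np.int64)
        self.ocb_flat = np.asarray(self.ocb_flat, dtype=np.int64)
        if self.pixels.ndim != 2:
            raise ShapeError("flattened pixels must be 2-D")
        n_cols = self.pixels.shape[1]
        if self.shift.shape != (n_cols,) or self.ocb_flat.shape != (n_cols,):
            raise ShapeError("shift/ocb_flat must have one entry per column")
        if (self.ocb_flat < 0).any():
            raise ValueError("ocb_flat must be non-negative")

    @property
    def crop_height(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    def slice_columns(self, start: int, stop: int) -> "FlattenedChoroid":
        return FlattenedChoroid(
            pixels=self.pixels[:, start:stop],
            shift=self.shift[start:stop],
            ocb_flat=self.ocb_flat[start:stop],
        )


def flatten_bscan(
    scan: BScan,
    boundaries: ChoroidBoundaries,
    crop_height: int,
) -> FlattenedChoroid:
    """Shift every A-scan so its ICB lands on row 0, then crop.

    Output pixel ``(r, c)`` equals input pixel ``(icb[c] + r, c)`` wherever
    that row exists; rows shifted in from below the scan are filled with 0.
    A warning is raised if ``crop_height`` clips the choroid of any column.
    """
    boundaries.validate_against(scan)
    if crop_height < 1:
        raise ValueError("crop_height must be at least 1")
    deepest = int((boundaries.ocb - boundaries.icb).max())
    if crop_height < deepest:
        warnings.warn(
            f"crop_height {crop_height} clips the choroid "
            f"(max thickness {deepest})",
            stacklevel=2,
        )
    rows, cols = scan.pixels.shape
    r = np.arange(crop_height)[:, None]
    src = boundaries.icb[None, :] + r                    # (crop_height, cols)
    in_range = src < rows
    out = np.zeros((crop_height, cols), dtype=scan.pixels.dtype)
    col_idx = np.broadcast_to(np.arange(cols)[None, :], src.shape)
    out[in_range] = scan.pixels[src[in_range], col_idx[in_range]]
    return FlattenedChoroid(
        pixels=out,
        shift=boundaries.icb.copy(),
        ocb_flat=boundaries.ocb - boundaries.icb,
    )


def unflatten(flat: FlattenedChoroid, n_rows: int) -> np.ndarray:
    """Scatter flattened pixels back to their original positions.

    Positions outside the flattened window are 0.  Used to check that
    flattening is invertible on in-range pixels.
    """
    cols = flat.n_cols
    out = np.zeros((n_rows, cols), dtype=flat.pixels.dtype)
    r = np.arange(flat.crop_height)[:, None]
    dst = flat.shift[None, :] + r
    in_range = dst < n_rows
    col_idx = np.broadcast_to(np.arange(cols)[None, :], dst.shape)
    out[dst[in_range], col_idx[in_range]] = flat.pixels[in_range]
    return out


def compute_crop_height(
    all_boundaries: Iterable[ChoroidBoundaries],
    scleral_margin: int = DEFAULT_SCLERAL_MARGIN,
) -> int:
    """Dataset-wide crop height: max choroidal thickness plus a sclera slab.

    The same value is applied to every image of a dataset so all flattened
    scans share one geometry.
    """
    maxima = [int((b.ocb - b.icb).max()) for b in all_boundaries]
    if not maxima:
        raise ValueError("need at least one boundary trace")
    if scleral_margin < 0:
        raise ValueError("scleral_margin must be non-negative")
    return max(maxima) + scleral_margin


def extract_subfoveal(
    flattened: FlattenedChoroid,
    width_mm: float = 6.0,
    lateral_scale_um: float = 14.0,
    center_column: int | None = None,
) -> FlattenedChoroid:
    """Extract the horizontally centered subfoveal strip of a given width.

    With the instrument's 14 µm transverse sampling a 6 mm strip is
    ``round(6000 / 14) = 429`` columns.  ``center_column`` defaults to the
    middle of the image (the fovea in a centered acquisition).
    """
    width_px = round(width_mm * 1000.0 / lateral_scale_um)
    if width_px < 1:
        raise ValueError("requested width is below one pixel")
    n_cols = flattened.n_cols
    if center_column is None:
        center_column = n_cols // 2
    start = center_column - width_px // 2
    stop = start + width_px
    if start < 0 or stop > n_cols:
        raise ValueError(
            f"subfoveal strip [{start}, {stop}) exceeds image width {n_cols}"
        )
    return flattened.slice_columns(start, stop)


__all__ = [
    "DEFAULT_SCLERAL_MARGIN",
    "FlattenedChoroid",
    "compute_crop_height",
    "extract_subfoveal",
    "flatten_bscan",
    "unflatten",
]
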