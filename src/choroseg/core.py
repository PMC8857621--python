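"""Core domain types and I/O for OCT choroid binarization.

The choroid is the vascular layer between the retina and the sclera.  In an
OCT B-scan it appears as a band of bright interstitial (stromal) tissue
containing dark vessel lumina, delimited by the inner choroidal boundary
(ICB, the RPE/Bruch's complex) above and the outer choroidal boundary (OCB,
the choroid-sclera transition) below.  This module holds the shared
containers — B-scans, boundary traces, per-pixel label maps — together with
the exact three-color encoding used for ground-truth label images:

* interstitial -> grey 0 (black)
* lumen        -> grey 255 (white)
* sclera       -> RGB (127, 0, 0)

Coordinates are 0-based; row 0 is the top of the image (inner retina) and
crops are half-open ``[start, stop)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image


class ChorosegError(Exception):
    """Base class for all package errors."""


class FormatError(ChorosegError):
    """Raised for files that decode but do not have the expected layout."""


class ShapeError(ChorosegError):
    """Raised when array shapes are inconsistent."""


class DecodingError(ChorosegError):
    """Raised when a label image contains a pixel outside the 3-color palette."""


class InvariantError(ChorosegError):
    """Raised when a domain invariant (e.g. OCB above ICB) is violated."""


class GenerationError(ChorosegError):
    """Raised when the phantom generator cannot satisfy its spec."""


class Category(IntEnum):
    """Pixel categories of the three-class choroid label map."""

    INTERSTITIAL = 0
    LUMEN = 1
    SCLERA = 2


#: RGB encoding of each category in ground-truth label images.
CATEGORY_COLORS: dict[Category, tuple[int, int, int]] = {
    Category.INTERSTITIAL: (0, 0, 0),
    Category.LUMEN: (255, 255, 255),
    Category.SCLERA: (127, 0, 0),
}

_PALETTE = np.array([CATEGORY_COLORS[c] for c in Category], dtype=np.uint8)


@dataclass(frozen=True)
class ScanID:
    """Identity of one B-scan within a longitudinal repeat-scan study."""

    subject: str = "unknown"
    visit: int = 1
    repeat: int = 1
    orientation: str = "horizontal"

    def __post_init__(self) -> None:
        if self.repeat not in (1, 2):
            raise ValueError(f"repeat must be 1 or 2, got {self.repeat}")
        if self.orientation not in ("horizontal", "vertical"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass
class BScan:
    """A single 8-bit grayscale OCT cross-section.

    Rows index axial depth (row 0 = inner retina), columns index A-scans.
    The axial/lateral scales are metadata in micrometres per pixel.
    """

    pixels: np.ndarray
    axial_scale_um: float = 3.9
    lateral_scale_um: float = 14.0
    scan_id: ScanID = field(default_factory=ScanID)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ShapeError("BScan pixels must be a non-empty 2-D array")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.axial_scale_um <= 0 or self.lateral_scale_um <= 0:
            raise ValueError("pixel scales must be positive")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ChoroidBoundaries:
    """Per-A-scan row indices of the inner and outer choroidal boundary."""

    icb: np.ndarray
    ocb: np.ndarray

    def __post_init__(self) -> None:
        self.icb = np.asarray(self.icb, dtype=np.int64)
        self.ocb = np.asarray(self.ocb, dtype=np.int64)
        if self.icb.ndim != 1 or self.icb.shape != self.ocb.shape:
            raise ShapeError("icb and ocb must be 1-D arrays of equal length")
        if (self.icb < 0).any():
            raise InvariantError("ICB rows must be non-negative")
        bad = np.nonzero(self.ocb < self.icb)[0]
        if bad.size:
            raise InvariantError(
                f"OCB above ICB at column(s) {bad[:5].tolist()}"
            )

    @property
    def n_cols(self) -> int:
        return self.icb.shape[0]

    def validate_against(self, scan: BScan) -> None:
        if self.n_cols != scan.n_cols:
            raise ShapeError(
                f"boundaries cover {self.n_cols} columns, scan has {scan.n_cols}"
            )
        if (self.ocb >= scan.n_rows).any():
            raise InvariantError("OCB extends below the bottom of the scan")

    def slice_columns(self, start: int, stop: int) -> "ChoroidBoundaries":
        return ChoroidBoundaries(self.icb[start:stop], self.ocb[start:stop])


@dataclass
class LabelMap:
    """Per-pixel category grid over {interstitial, lumen, sclera}."""

    categories: np.ndarray

    def __post_init__(self) -> None:
        self.categories = np.asarray(self.categories, dtype=np.uint8)
        if self.categories.ndim != 2:
            raise ShapeError("LabelMap must be 2-D")
        if self.categories.max(initial=0) > int(Category.SCLERA):
            raise ValueError("categories must be 0 (interstitial), 1 (lumen) or 2 (sclera)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.categories.shape

    def counts(self) -> dict[Category, int]:
        binc = np.bincount(self.categories.ravel(), minlength=3)
        return {c: int(binc[c]) for c in Category}

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, LabelMap):
            return NotImplemented
        return np.array_equal(self.categories, other.categories)


def as_categories(labels: "LabelMap | np.ndarray") -> np.ndarray:
    """Return the raw category grid of a LabelMap (or pass an array through)."""
    if isinstance(labels, LabelMap):
        return labels.categories
    return np.asarray(labels)


# ---------------------------------------------------------------------------
# label-map codec
# ---------------------------------------------------------------------------

def encode_labelmap(labels: LabelMap) -> np.ndarray:
    """Render a LabelMap as an (H, W, 3) uint8 color image.

    Interstitial pixels become black, lumen white and sclera the dark-red
    mask color (127, 0, 0) that highlights the region for network training.
    """
    return _PALETTE[as_categories(labels)]


def decode_labelmap(image: np.ndarray) -> LabelMap:
    """Invert :func:`encode_labelmap`; reject any off-palette pixel."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ShapeError("expected an (H, W, 3) color image")
    out = np.full(image.shape[:2], 255, dtype=np.uint8)
    for cat in Category:
        match = (image == _PALETTE[cat]).all(axis=2)
        out[match] = int(cat)
    bad = np.argwhere(out == 255)
    if bad.size:
        r, c = bad[0]
        raise DecodingError(
            f"pixel ({r}, {c}) has color {tuple(int(v) for v in image[r, c])}, "
            "not one of the 3 legal label colors"
        )
    return LabelMap(out)


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def read_bscan(
    path: str | Path,
    *,
    axial_scale_um: float = 3.9,
    lateral_scale_um: float = 14.0,
    scan_id: ScanID | None = None,
    convert_to_grayscale: bool = False,
) -> BScan:
    """Read an 8-bit grayscale PNG/TIFF as a BScan.

    Multi-channel images are rejected unless ``convert_to_grayscale`` is set,
    in which case Pillow's luminance conversion is applied.
    """
    try:
        img = Image.open(path)
        img.load()
    except (OSError, SyntaxError) as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if img.mode != "L":
        if not convert_to_grayscale:
            raise FormatError(
                f"{path} has mode {img.mode!r}; expected 8-bit grayscale "
                "(pass convert_to_grayscale=True to force conversion)"
            )
        img = img.convert("L")
    return BScan(
        pixels=np.asarray(img, dtype=np.uint8),
        axial_scale_um=axial_scale_um,
        lateral_scale_um=lateral_scale_um,
        scan_id=scan_id or ScanID(),
    )


def write_bscan(scan: BScan, path: str | Path) -> None:
    """Write a BScan as a lossless grayscale image (format from suffix)."""
    Image.fromarray(scan.pixels, mode="L").save(path)


def write_labelmap(labels: LabelMap, path: str | Path) -> None:
    """Write a label map as a 24-bit color PNG (lossless, palette-exact)."""
    path = Path(path)
    if path.suffix.lower() not in (".png",):
        raise FormatError("label maps must be stored as PNG to keep exact colors")
    Image.fromarray(encode_labelmap(labels), mode="RGB").save(path)


def read_labelmap(path: str | Path) -> LabelMap:
    """Read a color label image and decode it to a LabelMap."""
    img = Image.open(path).convert("RGB")
    return decode_labelmap(np.asarray(img, dtype=np.uint8))


# ---------------------------------------------------------------------------
# boundary-trace I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["column", "icb_row", "ocb_row"]


def read_boundaries(path: str | Path, n_columns: int | None = None) -> ChoroidBoundaries:
    """Read an ICB/OCB trace from CSV (``column,icb_row,ocb_row``) or JSON.

    The JSON dialect mirrors the CSV keys: an object with ``icb`` and ``ocb``
    lists.  If ``n_columns`` is given the trace length is checked against it.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        try:
            icb = np.asarray(data["icb"], dtype=np.int64)
            ocb = np.asarray(data["ocb"], dtype=np.int64)
        except KeyError as exc:
            raise FormatError(f"JSON boundary file {path} lacks key {exc}") from exc
    else:
        df = pd.read_csv(path)
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"boundary CSV {path} lacks column(s) {missing}")
        df = df.sort_values("column")
        icb = df["icb_row"].to_numpy(dtype=np.int64)
        ocb = df["ocb_row"].to_numpy(dtype=np.int64)
    if n_columns is not None and icb.shape[0] != n_columns:
        raise ShapeError(
            f"boundary trace has {icb.shape[0]} columns, expected {n_columns}"
        )
    return ChoroidBoundaries(icb=icb, ocb=ocb)


def write_boundaries(boundaries: ChoroidBoundaries, path: str | Path) -> None:
    """Write a boundary trace in the CSV or JSON dialect (from suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps({"icb": boundaries.icb.tolist(), "ocb": boundaries.ocb.tolist()})
        )
    else:
        pd.DataFrame(
            {
                "column": np.arange(boundaries.n_cols),
                "icb_row": boundaries.icb,
                "ocb_row": boundaries.ocb,
            }
        ).to_csv(path, index=False)


__all__ = [
    "BScan",
    "CATEGORY_COLORS",
    "Category",
    "ChoroidBoundaries",
    "ChorosegError",
    "DecodingError",
    "FormatError",
    "GenerationError",
    "InvariantError",
    "LabelMap",
    "ScanID",
    "ShapeError",
    "as_categories",
    "decode_labelmap",
    "encode_labelmap",
    "read_boundaries",
    "read_bscan",
    "read_labelmap",
    "write_boundaries",
    "write_bscan",
    "write_labelmap",
]
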