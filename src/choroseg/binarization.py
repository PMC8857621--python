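"""Niblack local thresholding of the flattened choroid.

The Niblack method computes a per-pixel threshold from the sliding window
centered on that pixel::

    T(i, j) = m(i, j) + k * sigma(i, j)

where ``m`` and ``sigma`` are the mean and (population) standard deviation
of the intensities inside the window and ``k`` weights the standard
deviation.  For choroidal OCT analysis ``k = -0.05``; dark pixels below the
threshold are vessel lumen, bright pixels at or above it are interstitial
stroma.  The window must be large enough to contain both tissue types but
small enough to preserve local detail, and the choroidal vascularity index
(CVI) is sensitive to this choice — hence the window-size sweep and the
explicit selection criterion that replace interactive tuning.

Numerics: windowed moments come from integral images over a symmetrically
padded copy of the data (every window is full, borders mirrored), computed
on globally centered values so the cumulative sums stay small and the map
matches a naive per-window evaluation to well below 1e-9.  Even window
sizes center at offset ``floor(w/2)`` inside the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Category, LabelMap, ShapeError, as_categories
from .flattening import FlattenedChoroid
from .metrics import cvi

#: Weight of the local standard deviation in the Niblack threshold.
DEFAULT_K = -0.05
#: Fixed-window baseline (mean of the manually selected window sizes).
FIXED_WINDOW = 51
#: Window-size sweep used to study CVI sensitivity.
SWEEP_WINDOWS = range(20, 76)
#: Smallest window offered by the interactive selection procedure.
MIN_INTERACTIVE_WINDOW = 5


@dataclass(frozen=True)
class NiblackParams:
    """Square sliding-window size and standard-deviation weight."""

    window: int = FIXED_WINDOW
    k: float = DEFAULT_K

    def __post_init__(self) -> None:
        if self.window < 3:
            raise ValueError("window must be at least 3 pixels")


def _window_sums(padded: np.ndarray, w: int, shape: tuple[int, int]) -> np.ndarray:
    """Sum of every w-by-w window of ``padded`` via an integral image."""
    ii = np.zeros((padded.shape[0] + 1, padded.shape[1] + 1), dtype=np.float64)
    np.cumsum(padded, axis=0, out=ii[1:, 1:])
    np.cumsum(ii[1:, 1:], axis=1, out=ii[1:, 1:])
    h, v = shape
    return ii[w : w + h, w : w + v] - ii[0:h, w : w + v] - ii[w : w + h, 0:v] + ii[0:h, 0:v]


def niblack_threshold_map(
    image: np.ndarray | FlattenedChoroid,
    params: NiblackParams | None = None,
    *,
    window: int | None = None,
    k: float | None = None,
) -> np.ndarray:
    """Per-pixel Niblack threshold ``T = m + k * sigma`` over a square window.

    ``sigma`` is the population standard deviation (divide by N) and borders
    are handled by symmetric (edge-mirroring) padding so every window is
    full.  Accepts either a ``NiblackParams`` or explicit keywords.
    """
    if isinstance(image, FlattenedChoroid):
        image = image.pixels
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ShapeError("expected a non-empty 2-D intensity grid")
    if params is None:
        params = NiblackParams(
            window=FIXED_WINDOW if window is None else window,
            k=DEFAULT_K if k is None else k,
        )
    w = params.window
    if w > 2 * min(image.shape):
        raise ValueError(
            f"window {w} is too large for a {image.shape[0]}x{image.shape[1]} image"
        )
    # center the data so the integral images keep full double precision
    c = image.mean()
    lo = w // 2
    hi = w - lo - 1
    padded = np.pad(image - c, ((lo, hi), (lo, hi)), mode="symmetric")
    n = float(w * w)
    s1 = _window_sums(padded, w, image.shape)
    s2 = _window_sums(padded * padded, w, image.shape)
    mean = s1 / n
    var = np.maximum(s2 / n - mean * mean, 0.0)
    return (mean + c) + params.k * np.sqrt(var)


def classify_choroid(
    image: np.ndarray | FlattenedChoroid,
    thresholds: np.ndarray,
    ocb_flat: np.ndarray | None = None,
) -> LabelMap:
    """Label each choroidal pixel lumen (below threshold) or interstitial.

    Ties go to interstitial: only strictly sub-threshold (hypo-reflective)
    pixels are lumen.  If an OCB trace is available — either from a
    ``FlattenedChoroid`` or the ``ocb_flat`` argument — rows at or below it
    are labelled sclera rather than classified.
    """
    if isinstance(image, FlattenedChoroid):
        if ocb_flat is None:
            ocb_flat = image.ocb_flat
        image = image.pixels
    image = np.asarray(image)
    thresholds = np.asarray(thresholds)
    if image.shape != thresholds.shape:
        raise ShapeError(
            f"image {image.shape} and threshold map {thresholds.shape} differ"
        )
    labels = np.where(
        image.astype(np.float64) < thresholds, Category.LUMEN, Category.INTERSTITIAL
    ).astype(np.uint8)
    out = LabelMap(labels)
    if ocb_flat is not None:
        out = mask_sclera(out, ocb_flat)
    return out


def mask_sclera(labels: LabelMap, ocb_flat: np.ndarray) -> LabelMap:
    """Set every pixel at or below the flattened OCB to the sclera category."""
    cats = as_categories(labels)
    ocb_flat = np.asarray(ocb_flat)
    if ocb_flat.shape != (cats.shape[1],):
        raise ShapeError("ocb_flat must have one entry per column")
    rows = np.arange(cats.shape[0])[:, None]
    out = cats.copy()
    out[rows >= ocb_flat[None, :]] = Category.SCLERA
    return LabelMap(out)


def binarize(
    flattened: FlattenedChoroid,
    params: NiblackParams | None = None,
    *,
    window: int | None = None,
    k: float | None = None,
) -> LabelMap:
    """Full Niblack step: threshold map, classification, sclera masking."""
    t = niblack_threshold_map(flattened, params, window=window, k=k)
    return classify_choroid(flattened, t)


def window_sweep_cvi(
    flattened: FlattenedChoroid,
    windows: Sequence[int] = SWEEP_WINDOWS,
    k: float = DEFAULT_K,
) -> list[tuple[int, float]]:
    """CVI of the binarized choroid for each requested window size.

    Reproduces the CVI-versus-window-size sensitivity analysis; the caller
    decides which strip (full scan or subfoveal region) to pass in.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("need at least one window size")
    out = []
    for w in windows:
        labels = binarize(flattened, window=w, k=k)
        out.append((int(w), float(cvi(labels))))
    return out


def select_window(
    sweep: Sequence[tuple[int, float]],
    truth: float | None = None,
) -> int:
    """Pick a window size from a (window, CVI) sweep.

    With a reference luminal fraction ``truth`` (in percent), returns the
    window whose CVI is nearest to it.  Without one, returns the left edge
    of the flattest stretch of the CVI curve: the window starting the
    segment with the smallest absolute CVI change to the next window, the
    smallest such window on ties.  This replaces interactive selection with
    a reproducible criterion.
    """
    sweep = sorted(sweep, key=lambda p: p[0])
    if not sweep:
        raise ValueError("empty sweep")
    if truth is not None:
        return min(sweep, key=lambda p: (abs(p[1] - truth), p[0]))[0]
    if len(sweep) == 1:
        return sweep[0][0]
    slopes = [
        abs(c2 - c1) / (w2 - w1)
        for (w1, c1), (w2, c2) in zip(sweep[:-1], sweep[1:])
    ]
    best = min(range(len(slopes)), key=lambda i: (slopes[i], sweep[i][0]))
    return sweep[best][0]


__all__ = [
    "DEFAULT_K",
    "FIXED_WINDOW",
    "MIN_INTERACTIVE_WINDOW",
    "NiblackParams",
    "SWEEP_WINDOWS",
    "binarize",
    "classify_choroid",
    "mask_sclera",
    "niblack_threshold_map",
    "select_window",
    "window_sweep_cvi",
]
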