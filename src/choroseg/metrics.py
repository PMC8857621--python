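"""Evaluation statistics for choroid binarization.

Accuracy is recall-style, ``TP / (TP + FN)`` per class, and the total
accuracy is the fraction of all pixels labelled correctly.  IoU is
``TP / (TP + FP + FN)`` per class with the mean taken over classes that
occur.  The choroidal vascularity index (CVI) is the luminal share of the
choroid, ``100 * lumen / (lumen + interstitial)``, with sclera excluded.
Repeatability between two scans of the same eye at the same visit is
``R = |P1 - P2| / p * 100`` where ``P1``/``P2`` are the pixel counts of a
category in each scan and ``p`` the total pixel count; 0 means perfect
agreement.  Paired per-eye measurements (e.g. CVI of scan 1 vs scan 2) are
summarized by a two-way random-effects, absolute-agreement, single-measure
intraclass correlation (ICC(2,1)) and by Bland-Altman mean difference with
95% limits of agreement (±1.96 sample SD of the differences).

Metrics with an empty denominator return NaN ("missing") rather than
raising, so degenerate classes never contaminate aggregate means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Category, LabelMap, ShapeError, as_categories

_N_CLASSES = 3


@dataclass
class ConfusionCounts:
    """3x3 pixel confusion matrix; ``matrix[t, p]`` counts truth t / pred p."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.shape != (_N_CLASSES, _N_CLASSES):
            raise ShapeError("confusion matrix must be 3x3")
        if (self.matrix < 0).any():
            raise ValueError("counts must be non-negative")

    def tp(self, cls: Category) -> int:
        return int(self.matrix[cls, cls])

    def fn(self, cls: Category) -> int:
        return int(self.matrix[cls].sum() - self.matrix[cls, cls])

    def fp(self, cls: Category) -> int:
        return int(self.matrix[:, cls].sum() - self.matrix[cls, cls])

    @property
    def n_pixels(self) -> int:
        return int(self.matrix.sum())

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.matrix + other.matrix)


@dataclass
class PairedSeries:
    """Per-eye measurements from scan 1 and scan 2 of the same visits."""

    values_scan1: np.ndarray
    values_scan2: np.ndarray

    def __post_init__(self) -> None:
        self.values_scan1 = np.asarray(self.values_scan1, dtype=np.float64)
        self.values_scan2 = np.asarray(self.values_scan2, dtype=np.float64)
        if (
            self.values_scan1.ndim != 1
            or self.values_scan1.shape != self.values_scan2.shape
        ):
            raise ShapeError("paired series must be equal-length 1-D arrays")
        if self.values_scan1.shape[0] < 2:
            raise ValueError("need at least 2 pairs")

    @property
    def n(self) -> int:
        return self.values_scan1.shape[0]

    def differences(self) -> np.ndarray:
        return self.values_scan1 - self.values_scan2


@dataclass
class MetricsReport:
    """Bundle of all evaluation outputs for one run."""

    total_accuracy: float
    per_class_accuracy: dict[str, float]
    per_class_iou: dict[str, float]
    mean_iou: float
    cvi_percent: float
    repeatability_R: dict[str, float] = field(default_factory=dict)
    icc: float = float("nan")
    mean_difference: float = float("nan")
    loa_halfwidth: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "total_accuracy": self.total_accuracy,
            "per_class_accuracy": dict(self.per_class_accuracy),
            "per_class_iou": dict(self.per_class_iou),
            "mean_iou": self.mean_iou,
            "cvi_percent": self.cvi_percent,
            "repeatability_R": dict(self.repeatability_R),
            "icc": self.icc,
            "mean_difference": self.mean_difference,
            "loa_halfwidth": self.loa_halfwidth,
        }


def confusion(pred: LabelMap | np.ndarray, truth: LabelMap | np.ndarray) -> ConfusionCounts:
    """Pixel-wise 3-class confusion counts between prediction and truth."""
    p = as_categories(pred)
    t = as_categories(truth)
    if p.shape != t.shape:
        raise ShapeError(f"prediction {p.shape} and truth {t.shape} differ")
    flat = _N_CLASSES * t.astype(np.int64).ravel() + p.astype(np.int64).ravel()
    counts = np.bincount(flat, minlength=_N_CLASSES * _N_CLASSES)
    return ConfusionCounts(counts.reshape(_N_CLASSES, _N_CLASSES))


def accuracy(counts: ConfusionCounts, cls: Category | None = None) -> float:
    """Per-class recall ``TP/(TP+FN)``, or the overall correct fraction."""
    if cls is None:
        total = counts.n_pixels
        if total == 0:
            return float("nan")
        return float(np.trace(counts.matrix) / total)
    denom = counts.tp(cls) + counts.fn(cls)
    if denom == 0:
        return float("nan")
    return counts.tp(cls) / denom


def iou(counts: ConfusionCounts, cls: Category) -> float:
    """Intersection over union ``TP/(TP+FP+FN)`` for one class."""
    denom = counts.tp(cls) + counts.fp(cls) + counts.fn(cls)
    if denom == 0:
        return float("nan")
    return counts.tp(cls) / denom


def mean_iou(counts: ConfusionCounts) -> float:
    """Mean IoU over the classes that occur in truth or prediction."""
    vals = [iou(counts, c) for c in Category]
    vals = [v for v in vals if not np.isnan(v)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def cvi(labels: LabelMap | np.ndarray) -> float:
    """Choroidal vascularity index: luminal percentage of the choroid.

    ``100 * lumen / (lumen + interstitial)``; sclera pixels are excluded,
    so the index only reflects the choroid band.  NaN when the map holds no
    choroidal pixel.
    """
    cats = as_categories(labels)
    binc = np.bincount(cats.ravel(), minlength=_N_CLASSES)
    lum = int(binc[Category.LUMEN])
    inter = int(binc[Category.INTERSTITIAL])
    if lum + inter == 0:
        return float("nan")
    return 100.0 * lum / (lum + inter)


def repeatability_R(
    labels1: LabelMap | np.ndarray,
    labels2: LabelMap | np.ndarray,
    cls: Category,
) -> float:
    """Absolute between-repeat difference in a category's pixel share (%).

    ``R = |P1 - P2| / p * 100`` with ``p`` the total pixel count of one
    image; 0 indicates perfect agreement between the two repeated scans.
    """
    c1 = as_categories(labels1)
    c2 = as_categories(labels2)
    if c1.shape != c2.shape:
        raise ShapeError(f"label maps {c1.shape} and {c2.shape} differ")
    p = c1.size
    n1 = int((c1 == cls).sum())
    n2 = int((c2 == cls).sum())
    return abs(n1 - n2) / p * 100.0


def icc(pairs: PairedSeries) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    The standard model for test-retest agreement of one instrument.  NaN
    when the data carry no variance at all.
    """
    import pingouin as pg

    if pairs.n < 3:
        raise ValueError("ICC needs at least 3 pairs")
    stacked = np.concatenate([pairs.values_scan1, pairs.values_scan2])
    if np.allclose(stacked, stacked[0]):
        return float("nan")
    if np.array_equal(pairs.values_scan1, pairs.values_scan2):
        return 1.0
    df = pd.DataFrame(
        {
            "eye": np.tile(np.arange(pairs.n), 2),
            "scan": np.repeat([1, 2], pairs.n),
            "value": stacked,
        }
    )
    table = pg.intraclass_corr(
        data=df, targets="eye", raters="scan", ratings="value"
    ).set_index("Type")
    # two-way random, absolute agreement, single measures; the label differs
    # across pingouin versions
    for label in ("ICC2", "ICC(A,1)"):
        if label in table.index:
            return float(table.loc[label, "ICC"])
    raise RuntimeError("ICC(2,1) row not found in pingouin output")


def bland_altman(pairs: PairedSeries) -> tuple[float, float]:
    """Mean difference (scan1 - scan2) and 95% LOA half-width.

    The half-width is ``1.96 * SD`` of the differences using the sample
    (n-1) standard deviation, so the limits of agreement are
    ``mean ± halfwidth``.
    """
    d = pairs.differences()
    mean_diff = float(d.mean())
    halfwidth = float(1.96 * d.std(ddof=1))
    return mean_diff, halfwidth


def evaluate(
    pred: LabelMap | np.ndarray,
    truth: LabelMap | np.ndarray,
    *,
    repeat_pred: LabelMap | np.ndarray | None = None,
    cvi_pairs: PairedSeries | None = None,
) -> MetricsReport:
    """Assemble a MetricsReport for one predicted/truth label-map pair.

    Optionally adds per-class repeatability against a second-repeat
    prediction and ICC/Bland-Altman over a paired CVI series.
    """
    counts = confusion(pred, truth)
    report = MetricsReport(
        total_accuracy=accuracy(counts),
        per_class_accuracy={c.name.lower(): accuracy(counts, c) for c in Category},
        per_class_iou={c.name.lower(): iou(counts, c) for c in Category},
        mean_iou=mean_iou(counts),
        cvi_percent=cvi(pred),
    )
    if repeat_pred is not None:
        report.repeatability_R = {
            c.name.lower(): repeatability_R(pred, repeat_pred, c) for c in Category
        }
    if cvi_pairs is not None:
        report.icc = icc(cvi_pairs)
        report.mean_difference, report.loa_halfwidth = bland_altman(cvi_pairs)
    return report


__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "PairedSeries",
    "accuracy",
    "bland_altman",
    "confusion",
    "cvi",
    "evaluate",
    "icc",
    "iou",
    "mean_iou",
    "repeatability_R",
]
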