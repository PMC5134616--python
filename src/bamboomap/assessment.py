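"""Accuracy assessment and canopy-density estimation.

Error matrices follow the rows-equal-predicted convention: row sums
give user's accuracy denominators, column sums producer's.  Overall
accuracy is trace / total and Cohen's kappa is (Po - Pe) / (1 - Pe)
with Pe = sum_m row_m * col_m / N^2.

Canopy density is the fraction of a fisheye photograph's valid
circular footprint covered by canopy; photographs are binarized with a
global Otsu threshold (sky bright, canopy dark, optionally inverted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .knn import ClassificationResult
from .samples import SampleSet

log = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """Class x class counts; rows are predicted, columns actual."""

    class_names: list[str]
    counts: np.ndarray  # (M, M) int, counts[predicted][actual]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        M = len(self.class_names)
        if self.counts.shape != (M, M):
            raise ValueError("counts must be square over class_names")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        """Serialized in the conventional layout: class rows with a
        user's-accuracy column and a producer's-accuracy row."""
        acc = accuracies(self)
        df = pd.DataFrame(self.counts, index=self.class_names,
                          columns=self.class_names)
        df["users_accuracy_pct"] = [acc["users"][c] for c in self.class_names]
        pa_row = {c: acc["producers"][c] for c in self.class_names}
        pa_row["users_accuracy_pct"] = acc["overall"]
        df.loc["producers_accuracy_pct"] = pd.Series(pa_row)
        df.attrs["orientation"] = "rows=predicted"
        return df


def confusion(pred: ClassificationResult, truth: SampleSet,
              class_names: list[str] | None = None) -> ConfusionMatrix:
    """Cross-tabulate predictions against reference labels.

    Only segments present in both are counted; reference segments with
    no prediction are logged.
    """
    pred_map = dict(zip(pred.segment_ids, pred.predicted))
    truth_ids = truth.df["segment_id"].to_numpy()
    truth_lab = truth.labels()
    if class_names is None:
        class_names = sorted(set(truth_lab) | set(pred.predicted))
    pos = {c: i for i, c in enumerate(class_names)}
    counts = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
    unmatched = skipped = 0
    for sid, actual in zip(truth_ids, truth_lab):
        if sid not in pred_map:
            unmatched += 1
            continue
        p = pred_map[sid]
        if p not in pos or actual not in pos:
            skipped += 1  # e.g. shadow, excluded from assessment
            continue
        counts[pos[p], pos[actual]] += 1
    if unmatched:
        log.warning("%d reference segments had no prediction", unmatched)
    if skipped:
        log.warning("%d pairs involved classes outside the assessed list",
                    skipped)
    return ConfusionMatrix(class_names=class_names, counts=counts)


def accuracies(cm: ConfusionMatrix) -> dict:
    """Producer's, user's and overall accuracy, in percent.

    Undefined accuracies (zero row or column) are reported as None, not
    0.  Values carry full precision; round for display.
    """
    counts = cm.counts.astype(np.float64)
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    diag = np.diag(counts)
    users = {c: (100.0 * diag[i] / rows[i] if rows[i] > 0 else None)
             for i, c in enumerate(cm.class_names)}
    producers = {c: (100.0 * diag[i] / cols[i] if cols[i] > 0 else None)
                 for i, c in enumerate(cm.class_names)}
    overall = 100.0 * diag.sum() / counts.sum()
    return {"users": users, "producers": producers, "overall": overall}


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: chance-corrected agreement."""
    counts = cm.counts.astype(np.float64)
    n = counts.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(counts) / n
    pe = float((counts.sum(axis=1) * counts.sum(axis=0)).sum()) / n ** 2
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1.0 - pe))


def round_display(x: float | None, ndigits: int = 2) -> float | None:
    """Half-up rounding for table display (Python's round is half-even)."""
    if x is None:
        return None
    from decimal import ROUND_HALF_UP, Decimal
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CanopyImage:
    """Binary canopy raster restricted to a circular fisheye footprint."""

    canopy: np.ndarray  # bool, True = canopy
    mask: np.ndarray    # bool, True = inside the fisheye footprint

    def __post_init__(self) -> None:
        if self.canopy.shape != self.mask.shape:
            raise ValueError("canopy and mask shapes differ")
        if not self.mask.any():
            raise ValueError("fisheye mask is empty")


def circular_mask(shape: tuple[int, int],
                  center: tuple[float, float] | None = None,
                  radius: float | None = None) -> np.ndarray:
    """Disk footprint mask; defaults to the largest centred disk."""
    rows, cols = shape
    if center is None:
        center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    if radius is None:
        radius = min(rows, cols) / 2.0
    rr, cc = np.indices(shape)
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def binarize_canopy(photo: np.ndarray, mask: np.ndarray | None = None,
                    canopy_is_dark: bool = True) -> CanopyImage:
    """Threshold a grayscale fisheye photo into canopy vs sky.

    Global Otsu threshold computed inside the footprint mask.  With
    ``canopy_is_dark`` (default), pixels at or below the threshold are
    canopy; flip the flag for inverted-polarity imagery.  A constant
    image is degenerate: flagged and treated as all-canopy.
    """
    img = np.asarray(photo, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("photo must be a single-channel grayscale image")
    if mask is None:
        mask = circular_mask(img.shape)
    vals = img[mask]
    if vals.max() == vals.min():
        log.warning("constant photo; degenerate threshold, whole footprint "
                    "treated as canopy")
        canopy = np.ones_like(img, dtype=bool)
    else:
        t = threshold_otsu(vals)
        canopy = img <= t if canopy_is_dark else img > t
    return CanopyImage(canopy=canopy & mask, mask=mask)


def canopy_density(img: CanopyImage) -> float:
    """Fraction of the footprint covered by canopy, in [0, 1]."""
    return float(img.canopy[img.mask].sum()) / float(img.mask.sum())
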