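"""Fixed-threshold (FT) and modified Otsu (OM) segmentation inside an
initialization VOI.

FT classifies every VOI voxel with value >= 42% (configurable) of the VOI
maximum as object.  OM adapts the threshold to the VOI histogram: because
SPECT voxel values are continuous, every unique value inside the VOI is
tried as a candidate threshold and the one maximizing the between-class
variance is chosen — no histogram binning is performed.  Any real threshold
strictly between two consecutive unique values yields the same
classification, so searching the unique values themselves is exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .imaging_core import BinaryMask3D, ScalarImage3D


class DegenerateHistogramError(ValueError):
    """Raised when the VOI contains fewer than two unique values."""


@dataclass
class ThresholdResult:
    threshold: float
    mask: BinaryMask3D
    method: Literal["FT", "OM"]


def fixed_threshold_segment(
    image: ScalarImage3D, init_voi: BinaryMask3D, fraction: float = 0.42
) -> ThresholdResult:
    """Segment by thresholding at ``fraction`` of the VOI maximum.

    Voxels inside the VOI with value >= threshold are classified as object.
    """
    if init_voi.is_empty():
        raise ValueError("initialization VOI is empty")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    voi_values = image.values[init_voi.member]
    vmax = voi_values.max()
    if vmax <= 0:
        raise ValueError("no object signal: VOI maximum is non-positive")
    threshold = fraction * vmax
    member = init_voi.member & (image.values >= threshold)
    return ThresholdResult(threshold, BinaryMask3D(image.grid, member), "FT")


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu threshold over continuous values: the unique value ``t``
    maximizing the between-class variance w0*w1*(mu0-mu1)^2 with class 0 the
    values <= t.

    Ties are broken toward the lowest candidate (larger object class).
    Returns one of the unique input values; classify with ``value > t``.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise DegenerateHistogramError("empty value list")
    uniq, counts = np.unique(values, return_counts=True)
    if uniq.size < 2:
        raise DegenerateHistogramError(
            f"need >= 2 unique values, got {uniq.size}"
        )
    n = values.size
    csum = np.cumsum(counts)
    cval = np.cumsum(counts * uniq)
    total = cval[-1]
    # candidates: every unique value except the largest (class 1 nonempty)
    n0 = csum[:-1]
    n1 = n - n0
    mu0 = cval[:-1] / n0
    mu1 = (total - cval[:-1]) / n1
    objective = (n0 / n) * (n1 / n) * (mu0 - mu1) ** 2
    best = int(np.argmax(objective))  # argmax takes the first (lowest) on ties
    return float(uniq[best])


def otsu_between_class_variance(values: np.ndarray, threshold: float) -> float:
    """Between-class variance of the split ``values <= threshold`` vs the rest."""
    values = np.asarray(values, dtype=float).ravel()
    low = values <= threshold
    n0, n1 = low.sum(), (~low).sum()
    if n0 == 0 or n1 == 0:
        return 0.0
    w0, w1 = n0 / values.size, n1 / values.size
    return float(w0 * w1 * (values[low].mean() - values[~low].mean()) ** 2)


def otsu_segment(image: ScalarImage3D, init_voi: BinaryMask3D) -> ThresholdResult:
    """Segment the VOI into background/object at the Otsu threshold; the
    high class (value > threshold) is the object."""
    if init_voi.is_empty():
        raise ValueError("initialization VOI is empty")
    t = otsu_threshold(image.values[init_voi.member])
    member = init_voi.member & (image.values > t)
    return ThresholdResult(t, BinaryMask3D(image.grid, member), "OM")
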