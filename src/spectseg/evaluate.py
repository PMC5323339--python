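"""Evaluation metrics: relative volume/concentration error statistics and
the cross-grid Dice similarity coefficient.

Given N repeated estimates V_i of a reference value V_ref, the relative
mean error, relative standard deviation and relative root-mean-square
error are

    E    = mean(V_i) / V_ref - 1                      (trueness)
    rSD  = sqrt( sum (V_i - mean)^2 / (N-1) ) / V_ref (precision)
    rRMSE= sqrt( sum (V_i - V_ref)^2 / N ) / V_ref    (accuracy)

linked by the identity rRMSE^2 = E^2 + rSD^2 * (N-1)/N.

The Dice coefficient is computed geometrically — voxels are treated as
rectangular cuboids and the exact intersection volume of the two cuboid
sets is accumulated — so masks living on grids with different voxel sizes
and origins can be compared without resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_core import BinaryMask3D, GridError


@dataclass
class ErrorStats:
    """Relative error statistics of repeated estimates against a reference."""

    mean_relative_error: float
    rsd: float  # nan (flagged undefined) when only one estimate is given
    rrmse: float
    n: int
    reference: float
    estimates: np.ndarray


def error_stats(estimates, reference: float) -> ErrorStats:
    """Relative mean error, rSD (N-1 denominator) and rRMSE (N denominator)
    of the estimates with respect to the reference.

    A single estimate yields a defined mean error and rRMSE but an
    undefined (NaN) rSD.
    """
    est = np.asarray(estimates, dtype=float).ravel()
    if est.size == 0:
        raise ValueError("empty estimate list")
    if reference <= 0:
        raise ValueError("reference must be positive")
    n = est.size
    mean = est.mean()
    e_bar = mean / reference - 1.0
    rsd = float(est.std(ddof=1) / reference) if n >= 2 else float("nan")
    rrmse = float(np.sqrt(np.mean((est - reference) ** 2)) / reference)
    return ErrorStats(float(e_bar), rsd, rrmse, n, float(reference), est)


@dataclass
class DSCResult:
    dsc: float
    overlap_cm3: float
    volume_a_cm3: float
    volume_b_cm3: float
    degenerate: bool = False


def _axis_intervals(mask: BinaryMask3D, axis: int, index: np.ndarray):
    """Cuboid face positions along one axis for the given voxel indices."""
    s = mask.grid.spacing[axis]
    o = mask.grid.origin[axis]
    lo = o + (index - 0.5) * s
    return lo, lo + s


def _overlap_matrix(mask_a: BinaryMask3D, mask_b: BinaryMask3D, axis: int,
                    idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Pairwise overlap length (mm) between the voxel intervals of the two
    grids along one axis."""
    lo_a, hi_a = _axis_intervals(mask_a, axis, idx_a)
    lo_b, hi_b = _axis_intervals(mask_b, axis, idx_b)
    return np.clip(
        np.minimum(hi_a[:, None], hi_b[None, :])
        - np.maximum(lo_a[:, None], lo_b[None, :]),
        0.0,
        None,
    )


def _bounding_slices(member: np.ndarray):
    idx = np.nonzero(member)
    return tuple(
        (int(ax.min()), int(ax.max()) + 1) for ax in idx
    )


def dice_cross_grid(mask_a: BinaryMask3D, mask_b: BinaryMask3D) -> DSCResult:
    """Dice similarity coefficient between masks on possibly different
    axis-aligned grids.

    The overlap is the exact summed intersection volume of the member
    cuboids of A with those of B, computed as a separable contraction of
    per-axis interval-overlap matrices restricted to the mask bounding
    boxes.  For masks on the same grid this reduces exactly to the
    classical voxel-count Dice.  Two empty masks give DSC 0 with the
    degeneracy flag set.
    """
    vol_a = mask_a.voxel_count * mask_a.grid.voxel_volume_mm3
    vol_b = mask_b.voxel_count * mask_b.grid.voxel_volume_mm3
    if vol_a == 0.0 and vol_b == 0.0:
        return DSCResult(0.0, 0.0, 0.0, 0.0, degenerate=True)
    if vol_a == 0.0 or vol_b == 0.0:
        return DSCResult(0.0, 0.0, vol_a / 1000.0, vol_b / 1000.0)

    bb_a = _bounding_slices(mask_a.member)
    bb_b = _bounding_slices(mask_b.member)
    sub_a = mask_a.member[tuple(slice(*b) for b in bb_a)].astype(float)
    sub_b = mask_b.member[tuple(slice(*b) for b in bb_b)].astype(float)
    # contract one axis at a time: T[a_x, a_y, a_z] -> T[b_x, a_y, a_z] -> ...
    t = sub_a
    for axis in range(3):
        idx_a = np.arange(bb_a[axis][0], bb_a[axis][1])
        idx_b = np.arange(bb_b[axis][0], bb_b[axis][1])
        m = _overlap_matrix(mask_a, mask_b, axis, idx_a, idx_b)
        t = np.tensordot(m.T, t, axes=([1], [0]))  # consumes leading axis
        t = np.moveaxis(t, 0, 2)
    overlap_mm3 = float(np.sum(t * sub_b))
    dsc = 2.0 * overlap_mm3 / (vol_a + vol_b)
    return DSCResult(dsc, overlap_mm3 / 1000.0, vol_a / 1000.0, vol_b / 1000.0)


def summarize_dsc(dscs) -> tuple[float, float, float]:
    """50th, 10th and 90th percentiles (linear interpolation between order
    statistics) of a list of Dice coefficients."""
    arr = np.asarray(dscs, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty DSC list")
    p50, p10, p90 = np.percentile(arr, [50, 10, 90], method="linear")
    return float(p50), float(p10), float(p90)
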