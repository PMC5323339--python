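"""Recovery-coefficient calibration and activity-concentration estimation.

Spill-out makes the measured concentration in a small hot object an
underestimate.  The recovery coefficient (RC) — the ratio of measured to
true concentration for an object of volume V — is modelled as

    R(V) = 1 / (1 + (a / V)**b)

with positive parameters a (the volume at which recovery is 50%) and b
(the steepness).  A tumour's activity concentration is then estimated as

    C = n / (R(V_tum) * eps * v_vox)

where n is the mean count rate per voxel in the tumour VOI, V_tum the VOI
volume, eps the system sensitivity (count rate per unit activity) and
v_vox the voxel volume.  Both n and R are evaluated with the same VOI, so
segmentation volume errors propagate into C through R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .imaging_core import BinaryMask3D, ScalarImage3D


@dataclass
class RCCurve:
    """Parameters of the recovery model R(V) = 1 / (1 + (a/V)^b).

    a is the half-recovery volume (cm^3), b the dimensionless steepness;
    both positive, so R is strictly increasing with R(a) = 0.5.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("RC parameters a and b must be positive")

    def __call__(self, volume_cm3) -> np.ndarray | float:
        v = np.asarray(volume_cm3, dtype=float)
        out = 1.0 / (1.0 + (self.a / v) ** self.b)
        return float(out) if out.ndim == 0 else out


@dataclass
class Calibration:
    """System sensitivity eps (count rate per unit activity) and voxel
    volume v_vox (cm^3)."""

    sensitivity: float
    v_vox_cm3: float

    def __post_init__(self) -> None:
        if self.sensitivity <= 0 or self.v_vox_cm3 <= 0:
            raise ValueError("sensitivity and voxel volume must be positive")


@dataclass
class ConcentrationEstimate:
    """Estimated concentration with its components: mean count rate per
    voxel n, VOI volume V_tum (cm^3), and the recovery R used."""

    concentration: float
    mean_counts_per_voxel: float
    volume_cm3: float
    recovery: float


@dataclass(frozen=True)
class VOICombination:
    """Which image the VOI was segmented on, and which image it is measured
    on — e.g. AS/ASR uses the AS-derived VOI on the ASR image."""

    source: str
    target: str

    def __str__(self) -> str:
        return f"{self.source}/{self.target}"


def calibration_from_count_scale(count_scale: float, v_vox_cm3: float) -> Calibration:
    """Calibration consistent with the phantom simulator: a count scale of
    k expected counts per unit concentration per voxel corresponds to a
    sensitivity of k / v_vox counts per unit activity."""
    return Calibration(sensitivity=count_scale / v_vox_cm3, v_vox_cm3=v_vox_cm3)


def sensitivity_from_planar(planar_counts: np.ndarray, activity: float) -> float:
    """System sensitivity from a planar acquisition of a known source:
    total counts (rate) in the projection divided by the source activity."""
    if activity <= 0:
        raise ValueError("activity must be positive")
    return float(np.sum(planar_counts) / activity)


def measure_rc(
    recon: ScalarImage3D,
    true_voi: BinaryMask3D,
    true_concentration: float,
    cal: Calibration,
) -> float:
    """Recovery coefficient: measured concentration in the true VOI divided
    by the true concentration."""
    if true_voi.is_empty():
        raise ValueError("true VOI is empty")
    if true_concentration <= 0:
        raise ValueError("true concentration must be positive")
    n = float(recon.values[true_voi.member].mean())
    measured = n / (cal.sensitivity * cal.v_vox_cm3)
    return measured / true_concentration


def fit_rc_curve(volumes_cm3, rcs) -> RCCurve:
    """Least-squares fit of the recovery model to (volume, RC) data.

    Unweighted residuals on the RC values; positivity of (a, b) enforced by
    optimizing their logarithms.  Requires >= 3 points with at least two
    RCs strictly inside (0, 1).
    """
    v = np.asarray(volumes_cm3, dtype=float)
    r = np.asarray(rcs, dtype=float)
    if v.size != r.size or v.size < 3:
        raise ValueError("need >= 3 (volume, rc) points")
    if np.count_nonzero((r > 0) & (r < 1)) < 2:
        raise ValueError("degenerate RC data: need >= 2 values strictly in (0, 1)")
    interior = (r > 0.0) & (r < 1.0)
    # initial a: volume whose RC is nearest 0.5; initial b: 1
    a0 = float(v[interior][np.argmin(np.abs(r[interior] - 0.5))])
    x0 = np.log([max(a0, 1e-6), 1.0])

    def residuals(x):
        a, b = np.exp(x)
        return 1.0 / (1.0 + (a / v) ** b) - r

    res = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    if not res.success:
        raise RuntimeError(f"RC fit did not converge: {res.message}")
    a, b = np.exp(res.x)
    return RCCurve(a=float(a), b=float(b))


def estimate_concentration(
    image: ScalarImage3D,
    voi: BinaryMask3D,
    rc: RCCurve,
    cal: Calibration,
) -> ConcentrationEstimate:
    """Activity concentration C = n / (R(V_tum) * eps * v_vox).

    The same VOI supplies both the mean count rate n and the volume at
    which the recovery curve is evaluated.
    """
    if voi.is_empty():
        raise ValueError("VOI is empty")
    v_tum = voi.voxel_count * cal.v_vox_cm3
    n = float(image.values[voi.member].mean())
    recovery = float(rc(v_tum))
    if recovery <= 0:
        raise ValueError(f"non-positive recovery {recovery} at V = {v_tum} cm^3")
    c = n / (recovery * cal.sensitivity * cal.v_vox_cm3)
    return ConcentrationEstimate(c, n, v_tum, recovery)


def apply_voi_combination(
    masks: dict[str, BinaryMask3D],
    images: dict[str, ScalarImage3D],
    combo: VOICombination,
    rc: RCCurve,
    cal: Calibration,
) -> ConcentrationEstimate:
    """Measure with the VOI segmented on one image type applied to another
    (or the same) image type."""
    if combo.source not in masks:
        raise KeyError(f"no segmentation mask for image tag {combo.source!r}")
    if combo.target not in images:
        raise KeyError(f"no image for tag {combo.target!r}")
    return estimate_concentration(images[combo.target], masks[combo.source], rc, cal)
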