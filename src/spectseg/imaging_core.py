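"""Voxel-grid data model, image/mask I/O, interpolation, gradients and morphology.

All grids are axis-aligned: voxel ``(i, j, k)`` has its centre at
``origin + (i*sx, j*sy, k*sz)`` in world millimetres, with 0-based indices.
Rotated or oblique orientations are rejected at load time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage


class GridError(ValueError):
    """Raised for malformed or unsupported voxel grids."""


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z).
    spacing : tuple of float
        Voxel size in mm along (x, y, z); all positive.
    origin : tuple of float
        World position (mm) of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise GridError(f"shape must be three positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GridError(f"spacing must be three positive floats, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid of voxel-centre world coordinates (mm), shape = grid shape."""
        axes = [
            self.origin[d] + self.spacing[d] * np.arange(self.shape[d])
            for d in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices of world points, shape (..., 3)."""
        points = np.asarray(points, dtype=float)
        return (points - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        indices = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + indices * np.asarray(self.spacing)

    def contains_point(self, points: np.ndarray) -> np.ndarray:
        """True where a world point lies within the voxel-centre hull."""
        idx = self.world_to_index(points)
        upper = np.asarray(self.shape) - 1
        return np.all((idx >= 0) & (idx <= upper), axis=-1)


@dataclass
class ScalarImage3D:
    """A scalar value per voxel (count rate per voxel, or activity concentration)."""

    grid: VoxelGrid
    values: np.ndarray
    units: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"value array shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")


@dataclass
class BinaryMask3D:
    """Boolean membership per voxel (a VOI)."""

    grid: VoxelGrid
    member: np.ndarray
    degenerate: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member).astype(bool)
        if self.member.shape != self.grid.shape:
            raise GridError(
                f"mask shape {self.member.shape} != grid shape {self.grid.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.member.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_cm3

    def is_empty(self) -> bool:
        return not self.member.any()


@dataclass
class VectorField3D:
    """Three scalar components per voxel (units: image-value per mm)."""

    grid: VoxelGrid
    components: np.ndarray  # shape (3, nx, ny, nz)

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape != (3, *self.grid.shape):
            raise GridError("component arrays must share the grid shape")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_METAIMAGE_SUFFIXES = (".mha", ".mhd")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _check_axis_aligned(direction: np.ndarray) -> None:
    direction = np.asarray(direction, dtype=float).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise GridError("grid must be axis-aligned")


def read_volume(path: str | Path) -> ScalarImage3D:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) scalar volume.

    Spacing and origin are taken from the header.  Non-axis-aligned
    orientations raise :class:`GridError` — rotation is unsupported.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        rot = affine[:3, :3]
        spacing = np.sqrt((rot**2).sum(axis=0))
        _check_axis_aligned(rot / spacing)
        # nibabel works in RAS mm; our convention keeps the stored axis order.
        values = np.asarray(img.dataobj, dtype=float)
        origin = affine[:3, 3]
    else:
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        _check_axis_aligned(np.array(img.GetDirection()))
        values = sitk.GetArrayFromImage(img).T.astype(float)  # sitk is (z,y,x)
        spacing = np.array(img.GetSpacing())
        origin = np.array(img.GetOrigin())
    grid = VoxelGrid(values.shape, tuple(spacing), tuple(origin))
    return ScalarImage3D(grid, values)


def write_volume(image: ScalarImage3D, path: str | Path) -> None:
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(image.grid.spacing)
        affine[:3, 3] = image.grid.origin
        nib.save(nib.Nifti1Image(image.values.astype(np.float32), affine), str(path))
    else:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(image.values.T.astype(np.float32))
        img.SetSpacing(image.grid.spacing)
        img.SetOrigin(image.grid.origin)
        sitk.WriteImage(img, str(path))


def read_mask(path: str | Path) -> BinaryMask3D:
    """Read a mask volume; any nonzero value maps to membership."""
    image = read_volume(path)
    return BinaryMask3D(image.grid, image.values != 0)


def write_mask(mask: BinaryMask3D, path: str | Path) -> None:
    """Write a mask as an unsigned 8-bit {0,1} volume."""
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(mask.grid.spacing)
        affine[:3, 3] = mask.grid.origin
        nib.save(nib.Nifti1Image(mask.member.astype(np.uint8), affine), str(path))
    else:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(mask.member.T.astype(np.uint8))
        img.SetSpacing(mask.grid.spacing)
        img.SetOrigin(mask.grid.origin)
        sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# Sampling and gradients
# ---------------------------------------------------------------------------


def trilinear_sample(image: ScalarImage3D, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the image at world points (mm).

    Points outside the voxel-centre hull return 0 (images are count maps
    whose background tends to zero).  Accepts a single point or an
    ``(..., 3)`` array.
    """
    points = np.asarray(points, dtype=float)
    single = points.ndim == 1
    pts = np.atleast_2d(points)
    idx = image.grid.world_to_index(pts)
    out = ndimage.map_coordinates(
        image.values, idx.T, order=1, mode="constant", cval=0.0
    )
    out = np.where(image.grid.contains_point(pts), out, 0.0)
    out = out.reshape(points.shape[:-1])
    return float(out) if single else out


def sample_vector_field(field3d: VectorField3D, points: np.ndarray) -> np.ndarray:
    """Trilinear sample of each component at world points; (..., 3) output."""
    points = np.asarray(points, dtype=float)
    pts = np.atleast_2d(points.reshape(-1, 3))
    idx = field3d.grid.world_to_index(pts)
    inside = field3d.grid.contains_point(pts)
    comps = [
        ndimage.map_coordinates(c, idx.T, order=1, mode="constant", cval=0.0)
        for c in field3d.components
    ]
    out = np.stack(comps, axis=-1)
    out[~inside] = 0.0
    return out.reshape(points.shape)


def make_vector_sampler(field3d: VectorField3D):
    """Compiled-down trilinear sampler for a vector field.

    Returns a function mapping world points of shape (P, 3) to sampled
    vectors (P, 3), zero outside the voxel-centre hull.  Precomputes the
    grid transform once; used in the inner loop of surface optimization
    where per-call overhead matters.
    """
    nx, ny, nz = field3d.grid.shape
    # rows = flattened voxels, columns = vector components: row gathers are cheap
    Gf = np.ascontiguousarray(field3d.components.reshape(3, -1).T)
    origin = np.asarray(field3d.grid.origin)
    spacing = np.asarray(field3d.grid.spacing)
    upper = np.array([nx - 1, ny - 1, nz - 1], dtype=float)
    strides = np.array([ny * nz, nz, 1], dtype=np.intp)

    def sample(pts: np.ndarray) -> np.ndarray:
        idx = (pts - origin) / spacing
        inside = np.all((idx >= 0) & (idx <= upper), axis=1)
        idx = np.clip(idx, 0.0, upper - 1e-9)
        i0 = idx.astype(np.intp)
        f = idx - i0
        base = i0 @ strides
        fx, fy, fz = f[:, 0, None], f[:, 1, None], f[:, 2, None]
        gx, gy, gz = 1.0 - fx, 1.0 - fy, 1.0 - fz
        sx, sy, sz = int(strides[0]), int(strides[1]), 1
        out = (
            Gf[base] * (gx * gy * gz)
            + Gf[base + sx] * (fx * gy * gz)
            + Gf[base + sy] * (gx * fy * gz)
            + Gf[base + sz] * (gx * gy * fz)
            + Gf[base + sx + sy] * (fx * fy * gz)
            + Gf[base + sx + sz] * (fx * gy * fz)
            + Gf[base + sy + sz] * (gx * fy * fz)
            + Gf[base + sx + sy + sz] * (fx * fy * fz)
        )
        out[~inside] = 0.0
        return out

    return sample


def _prewitt_gradient(values: np.ndarray, axis: int, spacing: float) -> np.ndarray:
    """Central difference along ``axis``, averaged over the 3x3 transverse
    neighbourhood, normalized to image-value per mm.

    Equivalent to convolution with a 3x3x3 antisymmetric kernel whose response
    to a unit-slope (per mm) ramp is exactly 1.
    """
    diff = np.zeros_like(values)
    sl_f = [slice(None)] * 3
    sl_b = [slice(None)] * 3
    sl_c = [slice(None)] * 3
    sl_f[axis] = slice(2, None)
    sl_b[axis] = slice(None, -2)
    sl_c[axis] = slice(1, -1)
    diff[tuple(sl_c)] = (values[tuple(sl_f)] - values[tuple(sl_b)]) / (2.0 * spacing)
    # one-sided differences at the two boundary slabs
    first = [slice(None)] * 3
    second = [slice(None)] * 3
    first[axis] = 0
    second[axis] = 1
    diff[tuple(first)] = (values[tuple(second)] - values[tuple(first)]) / spacing
    last = [slice(None)] * 3
    penult = [slice(None)] * 3
    last[axis] = values.shape[axis] - 1
    penult[axis] = values.shape[axis] - 2
    diff[tuple(last)] = (values[tuple(last)] - values[tuple(penult)]) / spacing
    # transverse 3x1 box smoothing on the other two axes
    for other in range(3):
        if other == axis:
            continue
        diff = ndimage.uniform_filter1d(diff, size=3, axis=other, mode="nearest")
    return diff


def image_gradient(image: ScalarImage3D) -> VectorField3D:
    """Gradient of the image by 3x3x3 smoothed-difference (Prewitt-style)
    convolutions along x, y and z, in image-value per mm."""
    if any(n < 3 for n in image.grid.shape):
        raise GridError("image_gradient requires at least 3 voxels per axis")
    comps = np.stack(
        [
            _prewitt_gradient(image.values, axis, image.grid.spacing[axis])
            for axis in range(3)
        ]
    )
    return VectorField3D(image.grid, comps)


# ---------------------------------------------------------------------------
# Binary morphology
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def binary_closing(mask: BinaryMask3D) -> BinaryMask3D:
    """Morphological closing (dilation then erosion) with a full 3x3x3 cube."""
    if mask.is_empty():
        return BinaryMask3D(mask.grid, np.zeros(mask.grid.shape, dtype=bool))
    closed = ndimage.binary_closing(mask.member, structure=_STRUCT_26)
    return BinaryMask3D(mask.grid, closed)


def largest_component(mask: BinaryMask3D) -> BinaryMask3D:
    """Largest 6-connected component of the mask (empty in → empty out)."""
    labels, n = ndimage.label(mask.member, structure=_STRUCT_6)
    if n == 0:
        return BinaryMask3D(mask.grid, np.zeros(mask.grid.shape, dtype=bool))
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return BinaryMask3D(mask.grid, labels == counts.argmax())


def solidify(mask: BinaryMask3D, seed: np.ndarray) -> BinaryMask3D:
    """Fill cavities and drop islands not connected to the seed point.

    Background is defined as the set of non-member voxels 6-connected to the
    grid border; everything else (members plus enclosed cavities) is labelled
    by 6-connectivity and the component containing the seed voxel is returned.
    If the seed falls in the background an empty mask is returned with its
    ``degenerate`` flag set.
    """
    seed = np.asarray(seed, dtype=float)
    idx = np.round(mask.grid.world_to_index(seed)).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(mask.grid.shape)):
        raise GridError(f"seed {tuple(seed)} lies outside the grid")
    # flood-fill the exterior from the border
    inv = ~mask.member
    labels, _ = ndimage.label(inv, structure=_STRUCT_6)
    border_labels = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            border_labels.update(np.unique(labels[tuple(sl)]))
    border_labels.discard(0)
    background = np.isin(labels, sorted(border_labels))
    solid = ~background
    comp_labels, _ = ndimage.label(solid, structure=_STRUCT_6)
    seed_label = comp_labels[tuple(idx)]
    if seed_label == 0:
        warnings.warn("solidify: seed lies in the background; returning empty mask")
        return BinaryMask3D(mask.grid, np.zeros(mask.grid.shape, dtype=bool), degenerate=True)
    return BinaryMask3D(mask.grid, comp_labels == seed_label)
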