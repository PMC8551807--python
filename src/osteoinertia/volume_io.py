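"""Density-volume I/O, gray/HU calibration, and bone segmentation.

A :class:`DensityVolume` stores CT data on the *gray* scale used for the
density and mass computations downstream: air maps to 0 and water to 1024,
i.e. ``gray = HU + 1024`` over the calibrated range [-1024, 4145] HU.
Physical coordinates follow the convention::

    physical = origin + orientation @ (index * spacing)

with 0-based voxel-center indices and arrays indexed (x, y, z).

File formats (NIfTI, MetaImage, DICOM series) are handled by SimpleITK.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "GRAY_OFFSET",
    "HU_MIN",
    "HU_MAX",
    "GRAY_MAX",
    "DensityVolume",
    "BoneMask",
    "VolumeFormatError",
    "CalibrationRangeError",
    "SegmentationEmptyError",
    "hu_to_gray",
    "gray_to_hu",
    "load_volume",
    "save_volume",
    "segment_bone",
]

GRAY_OFFSET = 1024.0
HU_MIN = -1024.0
HU_MAX = 4145.0
GRAY_MAX = HU_MAX + GRAY_OFFSET  # 5169


class VolumeFormatError(ValueError):
    """Input file does not parse as a 3-D density volume."""


class CalibrationRangeError(ValueError):
    """Value outside the calibrated HU/gray range."""


class SegmentationEmptyError(ValueError):
    """Thresholding produced an empty bone mask."""


@dataclass
class DensityVolume:
    """Gridded gray values with voxel geometry.

    Parameters
    ----------
    grid : (nx, ny, nz) ndarray
        Gray values (dimensionless; water = 1024).
    spacing : (3,) array-like
        Per-axis voxel size in mm, strictly positive.
    origin : (3,) array-like
        Scanner-frame position of the center of voxel (0, 0, 0), mm.
    orientation : (3, 3) ndarray
        Direction-cosine matrix (columns: image axes in the scanner frame);
        orthonormal with determinant +1.
    """

    grid: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.grid.ndim != 3:
            raise VolumeFormatError(
                f"density volume must be 3-D, got {self.grid.ndim}-D grid"
            )
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise VolumeFormatError("spacing must be 3 strictly positive values (mm)")
        if self.grid.size and (self.grid.min() < 0 or self.grid.max() > GRAY_MAX):
            raise CalibrationRangeError(
                f"gray values must lie in [0, {GRAY_MAX:.0f}]; "
                f"got [{self.grid.min():.1f}, {self.grid.max():.1f}]"
            )
        R = self.orientation
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise VolumeFormatError("orientation must be an orthonormal 3x3 matrix")
        if np.linalg.det(R) < 0:
            raise VolumeFormatError("orientation must have determinant +1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel-center indices to scanner-frame mm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin + (self.orientation @ (idx * self.spacing).T).T


@dataclass
class BoneMask:
    """Boolean mask congruent with a :class:`DensityVolume`."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise VolumeFormatError("bone mask must be 3-D")

    @property
    def voxel_count(self) -> int:
        """Number of bone voxels (the N of the mean-density formula)."""
        return int(self.mask.sum())


def hu_to_gray(hu):
    """Convert Hounsfield units to the gray scale (air 0, water 1024).

    Raises :class:`CalibrationRangeError` outside [-1024, 4145] HU.
    """
    hu = np.asarray(hu, dtype=float)
    if np.any(hu < HU_MIN) or np.any(hu > HU_MAX):
        raise CalibrationRangeError(
            f"HU outside calibrated range [{HU_MIN:.0f}, {HU_MAX:.0f}]"
        )
    out = hu + GRAY_OFFSET
    return float(out) if out.ndim == 0 else out


def gray_to_hu(gray):
    """Inverse of :func:`hu_to_gray`."""
    gray = np.asarray(gray, dtype=float)
    if np.any(gray < 0) or np.any(gray > GRAY_MAX):
        raise CalibrationRangeError(f"gray outside calibrated range [0, {GRAY_MAX:.0f}]")
    out = gray - GRAY_OFFSET
    return float(out) if out.ndim == 0 else out


_EXT_FORMATS = {
    ".nii": "nifti",
    ".nii.gz": "nifti",
    ".mha": "metaimage",
    ".mhd": "metaimage",
}


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "dicom_dir"
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return "nifti"
    ext = path.suffix.lower()
    if ext in _EXT_FORMATS:
        return _EXT_FORMATS[ext]
    raise VolumeFormatError(f"cannot infer volume format from {path.name!r}")


def _from_sitk(img: sitk.Image, values: str) -> DensityVolume:
    if img.GetDimension() != 3:
        raise VolumeFormatError(
            f"expected a 3-D volume, file holds {img.GetDimension()}-D data"
        )
    arr = sitk.GetArrayFromImage(img).astype(float)  # (z, y, x)
    grid = np.ascontiguousarray(arr.transpose(2, 1, 0))  # (x, y, z)
    if values == "hu":
        grid = np.clip(grid, HU_MIN, HU_MAX) + GRAY_OFFSET
    elif values != "gray":
        raise ValueError("values must be 'hu' or 'gray'")
    return DensityVolume(
        grid=grid,
        spacing=np.array(img.GetSpacing()),
        origin=np.array(img.GetOrigin()),
        orientation=np.array(img.GetDirection()).reshape(3, 3),
    )


def _read_dicom_dir(path: Path) -> sitk.Image:
    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(path))
    if not files:
        raise VolumeFormatError(f"no DICOM series found in {path}")
    # Reject ties in slice position along the stacking normal: silent
    # re-sorting of duplicate positions would corrupt the geometry.
    positions = []
    for f in files:
        one = sitk.ReadImage(f)
        positions.append(np.array(one.GetOrigin()))
    normal = positions[-1] - positions[0]
    norm = np.linalg.norm(normal)
    if norm > 0:
        proj = np.array([(p - positions[0]) @ normal / norm for p in positions])
        if len(np.unique(np.round(proj, 6))) != len(proj):
            raise VolumeFormatError(
                "duplicate slice positions along the stacking normal"
            )
    reader.SetFileNames(files)
    return reader.Execute()


def load_volume(path, format: str | None = None, values: str = "hu") -> DensityVolume:
    """Read a density volume from NIfTI, MetaImage, or a DICOM directory.

    Parameters
    ----------
    path : path-like
        File (NIfTI/MetaImage) or directory (DICOM series).
    format : {'nifti', 'metaimage', 'dicom_dir'}, optional
        Inferred from the extension when omitted.
    values : {'hu', 'gray'}
        Scale of the stored voxel values. HU input is converted to the
        gray scale; files written by :func:`save_volume` store gray.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    fmt = format or _infer_format(path)
    if fmt == "dicom_dir":
        img = _read_dicom_dir(path)
    elif fmt in ("nifti", "metaimage"):
        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as exc:  # pragma: no cover - ITK error text varies
            raise VolumeFormatError(f"could not parse {path}: {exc}") from exc
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return _from_sitk(img, values)


def save_volume(volume: DensityVolume, path, values: str = "gray") -> None:
    """Write a volume (gray scale by default) to NIfTI or MetaImage."""
    grid = volume.grid
    if values == "hu":
        grid = grid - GRAY_OFFSET
    elif values != "gray":
        raise ValueError("values must be 'hu' or 'gray'")
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.transpose(2, 1, 0)))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    img.SetDirection(tuple(volume.orientation.ravel()))
    os.makedirs(Path(path).parent or Path("."), exist_ok=True)
    sitk.WriteImage(img, str(path))


def save_mask(mask: BoneMask, volume: DensityVolume, path) -> None:
    """Write a bone mask as an 8-bit volume with the parent geometry."""
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(mask.mask.transpose(2, 1, 0).astype(np.uint8))
    )
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    img.SetDirection(tuple(volume.orientation.ravel()))
    sitk.WriteImage(img, str(path))


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (g**2).sum(axis=0) <= r**2


def segment_bone(
    volume: DensityVolume,
    lower: float,
    upper: float = GRAY_MAX,
    close_radius: int = 1,
    fill_holes: bool = False,
    keep_largest: bool = False,
) -> BoneMask:
    """Threshold the gray volume and close the result morphologically.

    The mask is ``lower <= gray <= upper`` followed by binary closing with
    a discrete ball of ``close_radius`` voxels. Hole filling and
    largest-component filtering are explicit opt-ins and are off by
    default, matching the reference reconstruction protocol.
    """
    if not lower < upper:
        raise ValueError(f"lower ({lower}) must be < upper ({upper})")
    if close_radius < 0:
        raise ValueError("close_radius must be >= 0")
    mask = (volume.grid >= lower) & (volume.grid <= upper)
    if not mask.any():
        raise SegmentationEmptyError(
            f"no voxels in gray range [{lower}, {upper}]"
        )
    if close_radius > 0:
        r = int(close_radius)
        structure = _ball(r)
        # pad so closing near the array border behaves as in open space
        padded = np.pad(mask, r, mode="constant", constant_values=False)
        padded = ndimage.binary_closing(padded, structure=structure)
        mask = padded[r:-r, r:-r, r:-r]
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    if keep_largest:
        labels, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
    return BoneMask(mask=mask)
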