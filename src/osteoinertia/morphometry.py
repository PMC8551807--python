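"""Per-bone geometric and inertial variables from an aligned bone.

Extracts the eight variables used for sex discrimination: normalized
length/width/height (fractions of their sum), surface-area-to-volume
ratio, mean density (gray/1024), and the three normalized principal
moments of inertia. Extents are measured on the surface mesh expressed in
the inertial body frame: length along z (long axis), width along y,
height along x.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure as _skmeasure

from .inertial_frame import (
    BodyFrame,
    mass_properties,
    principal_frame,
    to_body_frame,
)
from .volume_io import BoneMask, DensityVolume, GRAY_OFFSET

__all__ = [
    "SurfaceMesh",
    "GeometricMeasures",
    "BoneRecord",
    "NonWatertightMeshError",
    "MeasurementStageError",
    "extract_surface",
    "surface_and_volume",
    "extents",
    "normalize_triplet",
    "sa_to_v",
    "bone_density",
    "measure_bone",
]


class NonWatertightMeshError(ValueError):
    """Volume requested for a mesh that does not enclose space.

    The surface area is still available as the ``area`` attribute.
    """

    def __init__(self, message: str, area: float):
        super().__init__(message)
        self.area = area


class MeasurementStageError(RuntimeError):
    """A stage of the measurement pipeline failed; ``stage`` names it."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"measurement stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class SurfaceMesh:
    """Triangulated surface in mm; faces index into ``vertices``."""

    vertices: np.ndarray
    faces: np.ndarray
    watertight: bool

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    def transformed(self, func) -> "SurfaceMesh":
        """New mesh with ``func`` applied to the vertex array."""
        return SurfaceMesh(
            vertices=np.asarray(func(self.vertices), dtype=float),
            faces=self.faces,
            watertight=self.watertight,
        )


@dataclass
class GeometricMeasures:
    """Raw (un-normalized) positioned measures of one bone."""

    Lp: float  # extent along body z, mm
    Wp: float  # extent along body y, mm
    Hp: float  # extent along body x, mm
    S: float  # surface area, mm^2
    V: float  # enclosed volume, mm^3
    sa_v: float  # S / V, 1/mm
    density: float  # mean gray / 1024


@dataclass
class BoneRecord:
    """The eight normalized per-bone variables plus identifying metadata."""

    subject_id: str
    sex: str  # 'male' | 'female' | 'unknown'
    side: str  # 'left' | 'right'
    metatarsal: int  # 1..5
    Ln: float
    Wn: float
    Hn: float
    sa_v: float
    density: float
    pmi_x: float
    pmi_y: float
    pmi_z: float
    raw: GeometricMeasures | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "sex": self.sex,
            "side": self.side,
            "metatarsal": self.metatarsal,
            "Ln": self.Ln,
            "Wn": self.Wn,
            "Hn": self.Hn,
            "sa_v": self.sa_v,
            "density": self.density,
            "pmi_x": self.pmi_x,
            "pmi_y": self.pmi_y,
            "pmi_z": self.pmi_z,
        }


def extract_surface(
    mask: BoneMask,
    spacing: Sequence[float],
    iso: float = 0.5,
    smooth_sigma: float = 0.0,
) -> SurfaceMesh:
    """Marching-cubes isosurface of a binary mask, in physical mm.

    ``smooth_sigma`` (voxels) optionally Gaussian-filters the binary
    indicator before contouring. This anti-aliases the voxel staircase so
    that surface area becomes nearly independent of how the bone was
    oriented on the grid; 0 contours the raw binary mask.

    Vertex coordinates are ``index * spacing`` in the volume's index
    space; map them through the volume origin/orientation for
    scanner-frame positions.
    """
    if mask.voxel_count == 0:
        raise ValueError("empty mask")
    spacing = np.asarray(spacing, dtype=float)
    pad = 1 + int(np.ceil(3 * smooth_sigma))
    field_ = np.pad(mask.mask.astype(np.float32), pad)
    if smooth_sigma > 0:
        field_ = ndimage.gaussian_filter(field_, sigma=smooth_sigma)
    verts, faces, _, _ = _skmeasure.marching_cubes(
        field_, level=iso, spacing=tuple(spacing)
    )
    verts = verts - pad * spacing
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    return SurfaceMesh(vertices=verts, faces=faces, watertight=bool(tm.is_watertight))


def surface_and_volume(mesh: SurfaceMesh) -> tuple[float, float]:
    """Total triangle area and enclosed (divergence-theorem) volume.

    Volume is reported positive regardless of global face orientation.
    A non-watertight mesh raises :class:`NonWatertightMeshError` carrying
    the (still well-defined) area.
    """
    tm = mesh.as_trimesh()
    area = float(tm.area)
    if not tm.is_watertight:
        raise NonWatertightMeshError(
            "mesh is not watertight; enclosed volume undefined", area=area
        )
    return area, float(abs(tm.volume))


def extents(points: np.ndarray) -> tuple[float, float, float]:
    """(Lp, Wp, Hp): extents along body z, y, x of body-frame points."""
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 4:
        raise ValueError("need at least 4 points with 3 coordinates")
    centered = p - p.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(p).max())) < 3:
        raise ValueError("points are (nearly) coplanar; extents undefined")
    span = p.max(axis=0) - p.min(axis=0)
    return float(span[2]), float(span[1]), float(span[0])


def normalize_triplet(a: float, b: float, c: float) -> tuple[float, float, float]:
    """Fractions (a, b, c) / (a + b + c); inputs must be positive.

    Used for both the linear (Ln, Wn, Hn) and inertial (pmi_x, pmi_y,
    pmi_z) triplets; the published percent form is this times 100.
    """
    if a <= 0 or b <= 0 or c <= 0:
        raise ValueError("triplet entries must be strictly positive")
    s = a + b + c
    return a / s, b / s, c / s


def sa_to_v(S: float, V: float) -> float:
    """Surface-area-to-volume ratio S / V in 1/mm."""
    if V <= 0:
        raise ValueError("volume must be positive")
    if S <= 0:
        raise ValueError("surface area must be positive")
    return S / V


def bone_density(volume: DensityVolume, mask: BoneMask) -> float:
    """Mean gray/1024 over the bone voxels (dimensionless, water = 1)."""
    if mask.voxel_count == 0:
        raise ValueError("empty mask")
    return float(volume.grid[mask.mask].mean() / GRAY_OFFSET)


def measure_bone(
    volume: DensityVolume,
    mask: BoneMask,
    anatomical_refs=None,
    subject_id: str = "",
    sex: str = "unknown",
    side: str = "left",
    metatarsal: int = 1,
    weighting: str = "gray",
    smooth_sigma: float = 1.0,
) -> BoneRecord:
    """Full measurement pipeline: align, mesh, and normalize one bone.

    Runs mass properties -> principal frame -> body-frame transform ->
    surface extraction -> extents and normalizations. Deterministic for
    fixed inputs. ``smooth_sigma`` is passed to :func:`extract_surface`
    (default 1 voxel of isosurface anti-aliasing).
    """
    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage label
            raise MeasurementStageError(name, exc) from exc

    props = _stage("mass_properties", mass_properties, volume, mask, weighting)
    frame: BodyFrame = _stage("principal_frame", principal_frame, props, anatomical_refs)
    mesh = _stage("extract_surface", extract_surface, mask, volume.spacing,
                  smooth_sigma=smooth_sigma)
    S, V = _stage("surface_and_volume", surface_and_volume, mesh)
    verts_scanner = volume.origin + (volume.orientation @ mesh.vertices.T).T
    verts_body = to_body_frame(verts_scanner, frame)
    Lp, Wp, Hp = _stage("extents", extents, verts_body)
    Ln, Wn, Hn = normalize_triplet(Lp, Wp, Hp)
    pmi_x, pmi_y, pmi_z = normalize_triplet(*frame.axis_moments)
    ratio = sa_to_v(S, V)
    dens = _stage("bone_density", bone_density, volume, mask)
    raw = GeometricMeasures(Lp=Lp, Wp=Wp, Hp=Hp, S=S, V=V, sa_v=ratio, density=dens)
    return BoneRecord(
        subject_id=subject_id, sex=sex, side=side, metatarsal=metatarsal,
        Ln=Ln, Wn=Wn, Hn=Hn, sa_v=ratio, density=dens,
        pmi_x=pmi_x, pmi_y=pmi_y, pmi_z=pmi_z, raw=raw,
    )
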