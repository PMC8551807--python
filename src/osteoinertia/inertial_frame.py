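"""Mass properties and the inertial body frame of a segmented bone.

The bone's own coordinate system is defined from its mass distribution
alone: the origin is the center of mass (COM) and the axes are the
principal axes of inertia (PAI). For an elongated bone the long
(head-to-base) axis carries the smallest principal moment and is labeled
z; the remaining two axes are labeled x (plantar-dorsal) and y
(medial-lateral), either by matching user-supplied approximate anatomical
directions or, as a documented fallback, by eigenvalue order
(x = intermediate, y = largest moment).

Voxels are treated as point masses at voxel centers with mass
``gray / 1024`` (or 1 under uniform weighting); an optional cuboid
self-moment term adds each voxel's own moment about its center.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .volume_io import BoneMask, DensityVolume, GRAY_OFFSET

__all__ = [
    "MassProperties",
    "BodyFrame",
    "DegenerateFrameError",
    "mass_properties",
    "principal_frame",
    "to_body_frame",
    "from_body_frame",
]


class DegenerateFrameError(ValueError):
    """Principal moments too close to define a unique frame."""


@dataclass
class MassProperties:
    """Density-weighted rigid-body summary of a voxel set.

    ``total_mass`` is the sum of per-voxel masses (gray/1024, dimensionless
    mass units; multiply moments by the voxel volume to compare against
    closed forms expressed with mass density per mm^3). ``inertia_tensor``
    is taken about the COM in scanner-frame mm coordinates.
    """

    total_mass: float
    com: np.ndarray
    inertia_tensor: np.ndarray
    principal_moments: np.ndarray  # ascending
    principal_axes: np.ndarray  # columns, right-handed
    third_moment: np.ndarray  # central 3rd-order tensor, used for axis signs

    def __post_init__(self):
        I = self.inertia_tensor
        if not np.allclose(I, I.T, atol=1e-9 * max(1.0, float(np.abs(I).max()))):
            raise ValueError("inertia tensor must be symmetric")
        if np.any(self.principal_moments < -1e-9):
            raise ValueError("principal moments must be non-negative")


@dataclass
class BodyFrame:
    """COM origin plus a rotation whose rows are the body x, y, z axes."""

    origin: np.ndarray
    rotation: np.ndarray  # rows: x, y, z directions in the scanner frame
    axis_moments: np.ndarray  # (PMIx, PMIy, PMIz) raw values
    labeling: str = "anatomical"  # or "eigenvalue-order" fallback

    def __post_init__(self):
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be right-handed (det +1)")

    @property
    def pmi_x(self) -> float:
        return float(self.axis_moments[0])

    @property
    def pmi_y(self) -> float:
        return float(self.axis_moments[1])

    @property
    def pmi_z(self) -> float:
        return float(self.axis_moments[2])


def mass_properties(
    volume: DensityVolume,
    mask: BoneMask,
    weighting: str = "gray",
    voxel_self_moment: bool = False,
) -> MassProperties:
    """Compute COM, inertia tensor and principal decomposition of a mask.

    Parameters
    ----------
    volume, mask
        The density substrate and the bone voxels.
    weighting : {'gray', 'uniform'}
        Per-voxel mass gray/1024 (default) or 1.
    voxel_self_moment : bool
        Add each voxel's own cuboid moment about its center. Off by
        default (point-mass model); the omitted term is O(spacing^2).
    """
    if mask.mask.shape != volume.shape:
        raise ValueError("mask shape does not match volume")
    idx = np.argwhere(mask.mask)
    if idx.shape[0] == 0:
        raise ValueError("empty mask")
    if weighting == "gray":
        m = volume.grid[mask.mask] / GRAY_OFFSET
    elif weighting == "uniform":
        m = np.ones(idx.shape[0])
    else:
        raise ValueError("weighting must be 'gray' or 'uniform'")
    total = float(m.sum())
    if total <= 0:
        raise ValueError("total mass is zero under gray weighting")

    r = volume.index_to_physical(idx)  # (N, 3), mm
    com = (m[:, None] * r).sum(axis=0) / total
    rc = r - com
    sq = (rc**2).sum(axis=1)
    inertia = np.einsum("n,n->", m, sq) * np.eye(3) - np.einsum(
        "n,na,nb->ab", m, rc, rc
    )
    if voxel_self_moment:
        s = volume.spacing
        self_mom = np.diag((s**2).sum() - s**2) / 12.0
        inertia += total * self_mom
    third = np.einsum("n,na,nb,nc->abc", m, rc, rc, rc)

    moments, axes = np.linalg.eigh((inertia + inertia.T) / 2.0)
    if np.linalg.det(axes) < 0:
        axes[:, -1] *= -1
    return MassProperties(
        total_mass=total,
        com=com,
        inertia_tensor=inertia,
        principal_moments=moments,
        principal_axes=axes,
        third_moment=third,
    )


def _skewness_along(third: np.ndarray, e: np.ndarray) -> float:
    return float(np.einsum("abc,a,b,c->", third, e, e, e))


def principal_frame(
    props: MassProperties,
    anatomical_refs: Sequence[Sequence[float]] | None = None,
    degeneracy_gap: float = 1e-6,
) -> BodyFrame:
    """Label the principal axes as the body x, y, z frame.

    z is always the eigenvector of the smallest principal moment (the
    long axis). With ``anatomical_refs`` — three approximate scanner-frame
    directions ordered (x_ref, y_ref, z_ref) — the remaining axes are
    assigned by maximal \\|cosine\\| and signed to point along their
    references. Without references the fallback labels x = intermediate
    and y = largest moment, with signs fixed by the third central moment
    of mass (head-vs-base convention) and right-handedness.
    """
    lam = props.principal_moments
    scale = max(float(lam[-1]), np.finfo(float).tiny)
    gaps = np.diff(lam) / scale
    if np.any(gaps < degeneracy_gap) and anatomical_refs is None:
        raise DegenerateFrameError(
            "principal moments are (near-)degenerate; supply anatomical_refs "
            "to disambiguate the axis labeling"
        )
    v = [props.principal_axes[:, i] for i in range(3)]
    z = v[0]

    if anatomical_refs is not None:
        refs = np.asarray(anatomical_refs, dtype=float)
        if refs.shape != (3, 3):
            raise ValueError("anatomical_refs must be three 3-vectors (x, y, z)")
        refs = refs / np.linalg.norm(refs, axis=1, keepdims=True)
        x_ref, y_ref, z_ref = refs
        # assign the two remaining eigenvectors to x/y by maximal |cos|
        c = np.abs(np.array([[v[1] @ x_ref, v[1] @ y_ref],
                             [v[2] @ x_ref, v[2] @ y_ref]]))
        if c[0, 0] + c[1, 1] >= c[0, 1] + c[1, 0]:
            x, y = v[1], v[2]
            mom = (lam[1], lam[2], lam[0])
        else:
            x, y = v[2], v[1]
            mom = (lam[2], lam[1], lam[0])
        if z @ z_ref < 0:
            z = -z
        if x @ x_ref < 0:
            x = -x
        if y @ y_ref < 0:
            y = -y
        R = np.vstack([x, y, z])
        if np.linalg.det(R) < 0:
            # keep right-handedness by flipping the axis least aligned
            # with its reference (extents/PMIs are sign-invariant)
            dots = np.abs(np.array([x @ x_ref, y @ y_ref, z @ z_ref]))
            i = int(np.argmin(dots))
            R[i] *= -1
        return BodyFrame(
            origin=props.com, rotation=R, axis_moments=np.array(mom),
            labeling="anatomical",
        )

    # fallback: x = intermediate, y = largest moment
    x, y = v[1], v[2]
    mom = (lam[1], lam[2], lam[0])
    if _skewness_along(props.third_moment, z) < 0:
        z = -z
    sk_x = _skewness_along(props.third_moment, x)
    if sk_x < 0 or (sk_x == 0 and x[np.argmax(np.abs(x))] < 0):
        x = -x
    y = np.cross(z, x)
    R = np.vstack([x, y, z])
    return BodyFrame(
        origin=props.com, rotation=R, axis_moments=np.array(mom),
        labeling="eigenvalue-order",
    )


def to_body_frame(points: np.ndarray, frame: BodyFrame) -> np.ndarray:
    """Express scanner-frame points in the body frame: R (p - origin)."""
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    out = (np.atleast_2d(p) - frame.origin) @ frame.rotation.T
    return out[0] if single else out


def from_body_frame(points: np.ndarray, frame: BodyFrame) -> np.ndarray:
    """Inverse of :func:`to_body_frame`."""
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    out = np.atleast_2d(p) @ frame.rotation + frame.origin
    return out[0] if single else out
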