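"""Synthetic phantoms and simulated cohorts.

Two generators make every other module testable without any scan data:

* Voxel phantoms composed of primitives (ellipsoid, cuboid, cylinder,
  sphere) whose total mass, COM and inertia tensor have closed forms
  (parallel-axis composition), serving as the analytic oracle for the
  voxel mass-property code. Voxelization is by center-inclusion on a
  grid whose lattice is symmetric about the analytic COM.
* Cohorts of bone records drawn per sex from the published summary
  statistics (means/SDs clipped to the printed min/max by
  reject-and-redraw), with normalized triplets re-normalized to sum to 1.

Analytic mass properties use mass density gray/1024 per mm^3; the voxel
estimator counts point masses of gray/1024 per voxel, so voxel moments
times the voxel volume converge to the analytic values as spacing -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from . import reference_data as ref
from .inertial_frame import MassProperties
from .volume_io import BoneMask, DensityVolume, GRAY_OFFSET

__all__ = [
    "Primitive",
    "PhantomSpec",
    "CohortSpec",
    "make_phantom",
    "metatarsal_phantom",
    "random_rigid_transform",
    "simulate_cohort",
    "cohort_spec_from_reference",
]


@dataclass(frozen=True)
class Primitive:
    """One solid primitive with closed-form mass properties.

    ``size`` semantics per shape (mm): ellipsoid — semi-axes (a, b, c);
    cuboid — half-extents; sphere — (radius,); cylinder — (radius,
    half_height), axis along local z. ``gray`` is the uniform gray value
    (mass density gray/1024 per mm^3).
    """

    shape: str
    center: tuple[float, float, float]
    size: tuple[float, ...]
    gray: float = 1700.0
    rotation: tuple[tuple[float, ...], ...] = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    )

    def __post_init__(self):
        if self.shape not in ("ellipsoid", "cuboid", "sphere", "cylinder"):
            raise ValueError(f"unknown primitive shape {self.shape!r}")
        if any(s <= 0 for s in self.size):
            raise ValueError("primitive dimensions must be positive")

    @property
    def R(self) -> np.ndarray:
        return np.asarray(self.rotation, dtype=float)

    @property
    def density(self) -> float:
        return self.gray / GRAY_OFFSET

    def volume(self) -> float:
        s = self.size
        if self.shape == "ellipsoid":
            return 4.0 / 3.0 * np.pi * s[0] * s[1] * s[2]
        if self.shape == "sphere":
            return 4.0 / 3.0 * np.pi * s[0] ** 3
        if self.shape == "cuboid":
            return 8.0 * s[0] * s[1] * s[2]
        r, hh = s
        return np.pi * r**2 * 2 * hh

    def mass(self) -> float:
        return self.density * self.volume()

    def inertia_local(self) -> np.ndarray:
        """Inertia about the COM in the primitive's local axes."""
        m = self.mass()
        s = self.size
        if self.shape == "ellipsoid":
            a, b, c = s
            return m / 5.0 * np.diag([b**2 + c**2, a**2 + c**2, a**2 + b**2])
        if self.shape == "sphere":
            return 2.0 / 5.0 * m * s[0] ** 2 * np.eye(3)
        if self.shape == "cuboid":
            hx, hy, hz = s
            return m / 3.0 * np.diag([hy**2 + hz**2, hx**2 + hz**2, hx**2 + hy**2])
        r, hh = s
        it = m * (3 * r**2 + 4 * hh**2) / 12.0
        return np.diag([it, it, m * r**2 / 2.0])

    def inertia_world(self) -> np.ndarray:
        R = self.R
        return R @ self.inertia_local() @ R.T

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean center-inclusion test for (N, 3) mm points."""
        p = (np.asarray(points, dtype=float) - np.asarray(self.center)) @ self.R
        s = self.size
        if self.shape == "ellipsoid":
            return ((p / np.asarray(s)) ** 2).sum(axis=1) <= 1.0
        if self.shape == "sphere":
            return (p**2).sum(axis=1) <= s[0] ** 2
        if self.shape == "cuboid":
            return np.all(np.abs(p) <= np.asarray(s), axis=1)
        r, hh = s
        return (np.abs(p[:, 2]) <= hh) & (p[:, 0] ** 2 + p[:, 1] ** 2 <= r**2)

    def support(self, direction: np.ndarray) -> float:
        """Half-extent of the primitive along a unit direction (for bboxes)."""
        u = self.R.T @ np.asarray(direction, dtype=float)
        s = self.size
        if self.shape == "ellipsoid":
            return float(np.linalg.norm(np.asarray(s) * u))
        if self.shape == "sphere":
            return float(s[0])
        if self.shape == "cuboid":
            return float(np.abs(u) @ np.asarray(s))
        r, hh = s
        return float(hh * abs(u[2]) + r * np.hypot(u[0], u[1]))

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Primitive":
        return replace(
            self,
            center=tuple(R @ np.asarray(self.center) + np.asarray(t)),
            rotation=tuple(map(tuple, R @ self.R)),
        )


@dataclass
class PhantomSpec:
    """A composite solid with an analytic mass-property oracle."""

    primitives: list[Primitive]
    voxel_size: float = 0.4

    def __post_init__(self):
        if not self.primitives:
            raise ValueError("phantom needs at least one primitive")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    def analytic_mass_properties(self) -> MassProperties:
        """Closed-form mass, COM and inertia by parallel-axis composition.

        Primitives are assumed pairwise disjoint (overlap would be
        double-counted). Units: mass = density * mm^3; inertia mass*mm^2.
        """
        masses = np.array([p.mass() for p in self.primitives])
        centers = np.array([p.center for p in self.primitives], dtype=float)
        total = float(masses.sum())
        com = (masses[:, None] * centers).sum(axis=0) / total
        inertia = np.zeros((3, 3))
        for p, m, c in zip(self.primitives, masses, centers):
            d = c - com
            inertia += p.inertia_world()
            inertia += m * ((d @ d) * np.eye(3) - np.outer(d, d))
        moments, axes = np.linalg.eigh(inertia)
        if np.linalg.det(axes) < 0:
            axes[:, -1] *= -1
        return MassProperties(
            total_mass=total,
            com=com,
            inertia_tensor=inertia,
            principal_moments=moments,
            principal_axes=axes,
            third_moment=np.zeros((3, 3, 3)),
        )

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "PhantomSpec":
        return PhantomSpec(
            primitives=[p.transformed(R, t) for p in self.primitives],
            voxel_size=self.voxel_size,
        )


def make_phantom(
    spec: PhantomSpec, margin: float = 2.0
) -> tuple[DensityVolume, BoneMask, MassProperties]:
    """Voxelize a phantom and return it with its analytic oracle.

    Voxel centers sit at half-voxel offsets from the analytic COM, a
    lattice symmetric about the COM: a phantom symmetric about its COM
    voxelizes symmetrically (exact voxel COM), and flat faces at
    voxel-multiple distances do not land exactly on voxel centers.
    """
    h = spec.voxel_size
    analytic = spec.analytic_mass_properties()
    com = analytic.com
    axes_units = np.eye(3)
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for p in spec.primitives:
        c = np.asarray(p.center)
        for i in range(3):
            half = p.support(axes_units[i])
            lo[i] = min(lo[i], c[i] - half)
            hi[i] = max(hi[i], c[i] + half)
    lo -= margin
    hi += margin
    n_lo = np.ceil((com - lo) / h + 0.5).astype(int)
    n_hi = np.ceil((hi - com) / h + 0.5).astype(int)
    origin = com - (n_lo - 0.5) * h
    shape = n_lo + n_hi
    if np.any(shape < 1) or not np.all(np.isfinite(shape.astype(float))):
        raise ValueError("voxel_size too coarse for the phantom extent")

    ax = [origin[i] + h * np.arange(shape[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    grid = np.zeros(pts.shape[0])
    mask = np.zeros(pts.shape[0], dtype=bool)
    for p in spec.primitives:
        inside = p.contains(pts)
        newly = inside & ~mask
        grid[newly] = p.gray
        mask |= inside
    grid = grid.reshape(shape)
    mask = mask.reshape(shape)
    if not mask.any():
        raise ValueError("voxel_size too coarse: no voxel center falls inside")
    vol = DensityVolume(
        grid=grid, spacing=np.full(3, h), origin=origin, orientation=np.eye(3)
    )
    return vol, BoneMask(mask=mask), analytic


def metatarsal_phantom(voxel_size: float = 0.4, gray: float = 1700.0) -> PhantomSpec:
    """Idealized metatarsal: cylindrical shaft with two ellipsoidal ends.

    An elongated (z long axis), slightly anisotropic (x != y) and
    head/base-asymmetric body about 70 mm long — the scale of an adult
    metatarsal — with uniform density. Primitives touch the shaft end
    planes without overlap, so the analytic composition stays exact.
    """
    shaft = Primitive("cylinder", center=(0, 0, 0), size=(5.5, 20.0), gray=gray)
    head = Primitive("ellipsoid", center=(0, 0, -27.0), size=(6.5, 6.0, 7.0), gray=gray)
    base = Primitive("ellipsoid", center=(0, 0, 28.0), size=(9.0, 8.0, 8.0), gray=gray)
    return PhantomSpec(primitives=[shaft, head, base], voxel_size=voxel_size)


def random_rigid_transform(
    spec: PhantomSpec,
    seed: int | np.random.Generator | None = None,
    max_translation: float = 5.0,
) -> tuple[DensityVolume, BoneMask, tuple[np.ndarray, np.ndarray]]:
    """Re-voxelize a phantom under a random rotation + translation.

    The underlying geometry is transformed and voxelized afresh at the
    same spacing (no grid resampling), emulating the same bone scanned in
    a different posture. Returns the volume, mask and the applied
    ``(R, t)``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-max_translation, max_translation, size=3)
    moved = spec.transformed(R, t)
    vol, mask, _ = make_phantom(moved)
    return vol, mask, (R, t)


@dataclass
class CohortSpec:
    """Statistical recipe for a simulated cohort of bone records.

    ``stats`` maps variable -> sex -> (mean, sd, min, max); the defaults
    built by :func:`cohort_spec_from_reference` transcribe the published
    tables. Variables are drawn independently unless ``correlation`` (a
    positive semi-definite matrix over ``variables``) is given.
    ``sa_v_height_r`` optionally couples SA:V to body height within sex
    (Gaussian copula on the z-scores).
    """

    stats: Mapping[str, Mapping[str, ref.SummaryStat]]
    n_male: int = 30
    n_female: int = 30
    side: str = "left"
    metatarsal: int = 3
    variables: tuple[str, ...] = ref.VARIABLES
    correlation: np.ndarray | None = None
    covariates: Mapping[str, Mapping[str, tuple[float, float]]] | None = None
    sa_v_height_r: float = 0.0
    clip: bool = True

    def __post_init__(self):
        for v in self.variables:
            for sex in ("male", "female"):
                st = ref.SummaryStat(*self.stats[v][sex])
                if st.sd <= 0:
                    raise ValueError(f"SD must be positive for {v}/{sex}")
                if self.clip and st.min > st.max:
                    raise ValueError(f"infeasible clipping bounds for {v}/{sex}")
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
            if C.shape != (len(self.variables),) * 2:
                raise ValueError("correlation matrix shape mismatch")
            if np.linalg.eigvalsh((C + C.T) / 2).min() < -1e-10:
                raise ValueError("correlation matrix must be PSD")


def cohort_spec_from_reference(
    side: str = "left", metatarsal: int = 3, **overrides
) -> CohortSpec:
    """CohortSpec populated from the published per-bone summary tables."""
    stats = {
        v: dict(ref.COHORT_STATS[(side, metatarsal)][v]) for v in ref.VARIABLES
    }
    kw = dict(
        stats=stats, side=side, metatarsal=metatarsal,
        covariates=ref.DEFAULT_COVARIATES,
    )
    kw.update(overrides)
    return CohortSpec(**kw)


_TRIPLETS = (("Ln", "Wn", "Hn"), ("pmi_x", "pmi_y", "pmi_z"))


def _draw_group(spec: CohortSpec, sex: str, n: int, rng: np.random.Generator):
    p = len(spec.variables)
    if spec.correlation is not None:
        L = np.linalg.cholesky(
            np.asarray(spec.correlation, dtype=float) + 1e-12 * np.eye(p)
        )
    else:
        L = None

    z_height = rng.standard_normal(n)
    r = float(spec.sa_v_height_r)

    def draw(count):
        z = rng.standard_normal((count, p))
        return z @ L.T if L is not None else z

    z = draw(n)
    if r != 0.0 and "sa_v" in spec.variables:
        j = spec.variables.index("sa_v")
        z[:, j] = r * z_height + np.sqrt(1 - r**2) * z[:, j]

    means = np.array([spec.stats[v][sex][0] for v in spec.variables])
    sds = np.array([spec.stats[v][sex][1] for v in spec.variables])
    los = np.array([spec.stats[v][sex][2] for v in spec.variables])
    his = np.array([spec.stats[v][sex][3] for v in spec.variables])
    x = means + sds * z
    if spec.clip:
        # reject-and-redraw whole rows outside the printed range, keeping
        # the sampling distribution truncated rather than spiked at bounds
        for _ in range(10_000):
            bad = np.any((x < los) | (x > his), axis=1)
            if not bad.any():
                break
            zb = draw(int(bad.sum()))
            if r != 0.0 and "sa_v" in spec.variables:
                j = spec.variables.index("sa_v")
                zh = rng.standard_normal(int(bad.sum()))
                z_height[bad] = zh
                zb[:, j] = r * zh + np.sqrt(1 - r**2) * zb[:, j]
            x[bad] = means + sds * zb
        else:  # pragma: no cover - pathological bounds
            raise RuntimeError("rejection sampling did not converge")

    df = pd.DataFrame(x, columns=list(spec.variables))
    for trip in _TRIPLETS:
        if all(t in df.columns for t in trip):
            total = df[list(trip)].sum(axis=1)
            for t in trip:
                df[t] = df[t] / total
    df.insert(0, "sex", sex)
    if spec.covariates is not None:
        hm, hs = spec.covariates[sex]["height_cm"]
        df["height_cm"] = hm + hs * z_height
        wm, ws = spec.covariates[sex]["weight_kg"]
        df["weight_kg"] = wm + ws * rng.standard_normal(n)
    return df


def simulate_cohort(spec: CohortSpec, seed: int | None = 0) -> pd.DataFrame:
    """Draw a seeded, reproducible cohort of bone records.

    Returns a DataFrame in the cohort CSV schema: subject_id, sex, side,
    metatarsal, the eight variables, and (when covariates are configured)
    height_cm / weight_kg.
    """
    rng = np.random.default_rng(seed)
    males = _draw_group(spec, "male", spec.n_male, rng)
    females = _draw_group(spec, "female", spec.n_female, rng)
    df = pd.concat([males, females], ignore_index=True)
    df.insert(0, "subject_id", [f"S{i:03d}" for i in range(len(df))])
    df.insert(2, "side", spec.side)
    df.insert(3, "metatarsal", spec.metatarsal)
    return df
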