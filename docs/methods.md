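# Methods

This note documents the models, conventions and numerical choices behind
`osteoinertia`, and what the synthetic validation does and does not show.

## Density scale and segmentation

CT attenuation is handled on a shifted gray scale with air at 0 and
water at 1024 (`gray = HU + 1024`), calibrated over [-1024, 4145] HU.
The mapping is fixed by those two calibration points; values outside the
range raise rather than clamp. Segmentation is a two-sided gray
threshold followed by binary closing with a discrete ball (default
radius 1 voxel; the reference reconstruction software's exact kernel is
undocumented, so the radius is exposed). Hole filling and
largest-component filtering are deliberate opt-ins, off by default to
match the reference protocol. The bone threshold itself is a required
parameter of the CLI: the reference protocol deselected the predefined
bone threshold set without stating the value used, so no silent default
is defensible.

Coordinates: 0-based voxel-center indices, arrays indexed (x, y, z),
`physical = origin + orientation @ (index * spacing)`. DICOM series are
stacked along the position normal; duplicate slice positions are an
error, never silently re-sorted.

## Mass properties and the body frame

Voxels are point masses at voxel centers, mᵢ = gᵢ/1024 (or 1 under
uniform weighting). The inertia tensor about the COM is the standard
rigid-body sum I = Σ mᵢ(|rᵢ|²E − rᵢrᵢᵀ) in physical mm. The point-mass
model omits each voxel's own second moment, an O(spacing²) term; an
optional cuboid self-moment correction is available and demonstrably
reduces the error on coarse grids. `total_mass` is Σ mᵢ, so voxel
moments times the voxel volume are the quantities that converge to
closed forms expressed with density per mm³.

The body frame takes the eigenvector of the smallest principal moment
as z (the long, head-to-base axis — elongated bones concentrate mass
along it). The remaining two axes are anatomically ambiguous from
eigenvalues alone: in the reference data the relative order of the x and
y moments flips between metatarsals 1/5 and 2–4, so no eigenvalue rule
can reproduce anatomy everywhere. The implementation therefore accepts
three approximate anatomical reference directions (e.g. scanner "up"
from a known scanning posture) and assigns x/y by maximal |cosine|;
without references it falls back to x = intermediate, y = largest
moment, and records that fallback on the frame. Axis signs are fixed by
the references, or by the sign of the third central moment of mass
along the axis (a head-vs-base stand-in convention — the reference
method's automatic head/base resolution is unpublished), with
right-handedness enforced by flipping the least-constrained axis when
needed. None of the eight measured variables depends on axis signs;
extents and moments are sign-invariant, so sign conventions only
stabilize visual output and serialization.

Near-degenerate moment spectra (relative gap below 1e-6) raise a
degeneracy error unless references are supplied; a sphere-like bone has
no well-defined frame and the error says what to do about it.

## Surface, extents and the eight variables

The surface is a marching-cubes isosurface of the binary mask at level
0.5, padded so the mesh always closes. Plain binary contouring carries
an orientation-dependent staircase bias of several percent in surface
area; the measurement pipeline therefore Gaussian-filters the binary
indicator (sigma = 1 voxel) before contouring. This is isosurface
anti-aliasing, not mesh smoothing: it recovers the smooth surface a
sub-voxel reconstruction would give (sphere area error drops from ~9% to
~0.1% at 0.25 mm) and makes surface area nearly posture-independent.
`extract_surface` itself defaults to sigma = 0 (raw binary), and sharp-
edged solids are better served by it — smoothing rounds true corners.

Surface area is the triangle-area sum; volume comes from the divergence
theorem and is reported positive regardless of global orientation;
non-watertight meshes raise, with the area still attached to the error.
Extents are measured on surface-mesh vertices expressed in the body
frame (voxel-center extents would shrink every dimension by half a
voxel): length along z, width along y, height along x. Both triplets —
(Lp, Wp, Hp) and the raw principal moments — are normalized to fractions
of their sum; the published presentation multiplies by 100, which is
treated as display only since the printed fractions sum to ≈1. Density
is the mean of gᵢ/1024 over mask voxels; SA:V is S/V in 1/mm.

## Dimorphism statistics

SDI uses group means; it is antisymmetric and scale-invariant by
construction. Between-sex comparisons run Shapiro–Wilk per sex and
Levene (mean-centered, matching common statistical-package defaults) at
alpha = 0.05: both normal and homoscedastic → pooled t; normal but
heteroscedastic → Welch; otherwise Mann–Whitney U. Normality is judged
per sex, not pooled. No multiple-testing correction is applied by
default (raw p-values at 0.05/0.01 are the convention this pipeline
mirrors); a Holm option exists on the caller's side by adjusting the
returned p-values.

The assumption battery computes Mardia's multivariate skewness
(n·b₁ₚ/6 against chi-square with p(p+1)(p+2)/6 df, ML covariance
scaling) and kurtosis (normal approximation), per-record Mahalanobis
distances within sex against chi-square(p) with outliers at p < 0.001,
and Box's M via pingouin with a pass at p > 0.001. Both 0.001 thresholds
are configurable. Singular covariances are reported with the names of
the collinear variables. ICC defaults to the single-measurement,
absolute-agreement two-way form (McGraw–Wong ICC(A,1)): the two "raters"
are repeat scan/reconstructions of the same bones, so absolute agreement
— not consistency — is the relevant question; the form is a parameter.

## Discriminant analysis

The canonical direction is a ∝ S_w⁻¹(μ_m − μ_f) with S_w the pooled
within-group covariance (n − g divisor), scaled to unit pooled
within-group score variance and shifted so the overall (case-weighted)
mean score is 0. Centroids are scores at group means; equal priors put
the sectioning point at their midpoint; classification takes the male
side of it, with exact ties labeled indeterminate. Standardized
coefficients are aᵢ·√(S_w)ᵢᵢ; the structure matrix is the pooled
within-group correlation between each variable and the score,
(S_w a)ᵢ/√(S_w)ᵢᵢ. Wilks' Λ = det(W)/det(T) over the within/total SSCP
matrices; its chi-square uses Bartlett's correction
−(n − 1 − (p + g)/2)·ln Λ.

Stepwise selection enters the candidate minimizing Λ subject to
F-to-enter = ((Λ_p/Λ_{p+1}) − 1)(n − g − p)/(g − 1) ≥ 3.84 (p = current
model size), then removes any included variable whose F-to-remove drops
below 2.71, until stable; a cycle guard caps the loop. An empty model is
a result, not an error. The canonical sign is arbitrary; fitted models
orient the largest-|standardized-coefficient| variable positive, while
the published registry keeps printed signs verbatim — classification is
invariant either way. Leave-one-out keeps the selected variable set
fixed and refits coefficients per fold (the cross-validation semantics
of the stepwise-discriminant software the reference results come from);
full per-fold re-selection is available behind a flag.

Reproduction tolerances: published centroids are recovered from printed
group means only to ±0.05, because 3-decimal rounding of the means meets
coefficients of magnitude up to ~65.

## Synthetic data

Phantoms compose ellipsoids, cuboids, spheres and cylinders with exact
mass, COM and inertia (parallel-axis composition; primitives must be
pairwise disjoint). Voxelization is center-inclusion on a lattice at
half-voxel offsets from the analytic COM: symmetric solids then voxelize
symmetrically (exact COM), and flat faces at voxel-multiple distances
avoid degenerate boundary inclusion. The metatarsal preset — a
cylindrical shaft with two unequal ellipsoidal ends, ~70 mm long,
uniform gray 1700 (d ≈ 1.66, inside the published density range) — is
elongated, x/y-anisotropic and head/base-asymmetric, the features the
frame construction needs. Random rigid motions transform the geometry
and re-voxelize at the same spacing, emulating a different scanning
posture without resampling error.

Cohorts draw per-sex multivariate normals from the transcribed published
summary statistics (mean, SD, min, max per variable, sex, side and
metatarsal). Variables are independent by default — the reference tables
publish no covariance matrix — so simulated multivariate quantities
(stepwise selections, LOO accuracies, Box's M outcomes) are
approximations to, not reproductions of, the real cohort's. Rows outside
the printed min/max are rejected and redrawn (no truncation spikes), and
both normalized triplets are re-normalized to sum to exactly 1. Per-sex
body height/weight are not published; the defaults (male 177.5 ± 6.0 cm,
68.5 ± 8.0 kg; female 164.3 ± 6.0 cm, 56.5 ± 6.0 kg) are chosen so the
pooled 30 + 30 cohort reproduces the published pooled 170.9 ± 9.9 cm and
62.5 ± 10.6 kg. An optional within-sex SA:V–height coupling (Gaussian
copula on z-scores) is off by default; notably, the pooled SA:V–height
Spearman correlation already lands in the published 0.60–0.81 magnitude
band from the between-sex body-size difference alone.

## Problem sizes used in validation

Closed-form oracle checks run at 0.25 mm voxels (COM exact for symmetric
phantoms, principal moments within 1%); the rigid-motion equivariance
sweep uses 100 seeded transforms of the metatarsal preset at 0.4 mm
(all eight normalized variables vary with relative SD below 1.5%,
observed ≈0.2%); the stepwise oracle comparison uses 200 random cohorts
with n ≤ 20 and p ≤ 3 against an independent regression-based route
(two-group Wilks' Λ equals 1 − R² of the group-indicator regression);
the classification band uses 100 simulated 30 + 30 cohorts. These sizes
make the whole suite run in a couple of minutes on one core.

## What passing tests do not show

Simulated cohorts share the published means and SDs but not the real
inter-variable covariance, non-normality or outlier structure, so
simulated accuracies characterize the method under the published
marginals, not the authors' subjects. Phantoms have uniform density and
smooth analytic surfaces: no trabecular microstructure, scanner noise,
beam hardening or partial-volume gradients. The anatomical x/y labeling
on real bones requires reference directions or landmark knowledge the
fallback cannot supply, and the head-vs-base sign convention is a
documented stand-in. Densities are unitless HU ratios, not calibrated
mg/cm³ BMD.
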