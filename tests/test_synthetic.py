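"""Phantom voxelization against closed forms; cohort simulator statistics."""

import numpy as np
import pandas as pd
import pytest

from osteoinertia import inertial_frame as inf
from osteoinertia import reference_data as ref
from osteoinertia.synthetic import (
    CohortSpec,
    PhantomSpec,
    Primitive,
    cohort_spec_from_reference,
    make_phantom,
    metatarsal_phantom,
    random_rigid_transform,
    simulate_cohort,
)


class TestPrimitives:
    def test_closed_form_volumes(self):
        assert Primitive("sphere", (0, 0, 0), (2.0,)).volume() == pytest.approx(
            4 / 3 * np.pi * 8
        )
        assert Primitive("cuboid", (0, 0, 0), (1.0, 2.0, 3.0)).volume() == 48.0
        assert Primitive("cylinder", (0, 0, 0), (2.0, 5.0)).volume() == pytest.approx(
            np.pi * 4 * 10
        )

    def test_degenerate_primitive_rejected(self):
        with pytest.raises(ValueError):
            Primitive("ellipsoid", (0, 0, 0), (1.0, 0.0, 1.0))
        with pytest.raises(ValueError):
            Primitive("pyramid", (0, 0, 0), (1.0,))

    def test_analytic_tensor_is_psd_symmetric(self):
        spec = metatarsal_phantom()
        props = spec.analytic_mass_properties()
        I = props.inertia_tensor
        assert np.allclose(I, I.T)
        assert np.linalg.eigvalsh(I).min() >= 0


class TestMakePhantom:
    def test_sphere_voxel_volume(self):
        spec = PhantomSpec(
            [Primitive("sphere", (0, 0, 0), (10.0,))], voxel_size=0.25
        )
        vol, mask, _ = make_phantom(spec)
        assert mask.voxel_count * vol.voxel_volume == pytest.approx(
            4 / 3 * np.pi * 1000, rel=0.01
        )

    def test_ellipsoid_moments_converge_to_closed_form(self):
        spec = PhantomSpec(
            [Primitive("ellipsoid", (0, 0, 0), (30.0, 10.0, 8.0))], voxel_size=0.4
        )
        vol, mask, analytic = make_phantom(spec)
        props = inf.mass_properties(vol, mask)
        est = np.sort(props.principal_moments) * vol.voxel_volume
        assert np.allclose(est, np.sort(analytic.principal_moments), rtol=0.01)

    def test_convergence_rate_with_voxel_size(self):
        errs = []
        for h in (1.0, 0.5, 0.25):
            spec = PhantomSpec(
                [Primitive("ellipsoid", (0, 0, 0), (15.0, 6.0, 5.0))], voxel_size=h
            )
            vol, mask, analytic = make_phantom(spec)
            props = inf.mass_properties(vol, mask)
            est = np.sort(props.principal_moments) * vol.voxel_volume
            errs.append(
                np.abs(est / np.sort(analytic.principal_moments) - 1).max()
            )
        assert errs[2] < errs[0]
        assert errs[2] < 0.01

    def test_composite_parallel_axis_composition(self):
        # two equal disjoint spheres: analytic tensor must equal the
        # hand-written parallel-axis sum, and the voxel estimate agree
        r, d = 6.0, 8.0
        spec = PhantomSpec(
            [
                Primitive("sphere", (-d, 0, 0), (r,)),
                Primitive("sphere", (d, 0, 0), (r,)),
            ],
            voxel_size=0.4,
        )
        analytic = spec.analytic_mass_properties()
        m1 = spec.primitives[0].mass()
        eye_term = 2 * (2 / 5 * m1 * r**2)
        expected = np.diag([
            eye_term,
            eye_term + 2 * m1 * d**2,
            eye_term + 2 * m1 * d**2,
        ])
        assert np.allclose(analytic.inertia_tensor, expected)
        vol, mask, _ = make_phantom(spec)
        props = inf.mass_properties(vol, mask)
        est = np.sort(props.principal_moments) * vol.voxel_volume
        # 0.4 mm is coarse for r = 6 mm spheres; finer grids are covered
        # by the convergence test above
        assert np.allclose(est, np.sort(analytic.principal_moments), rtol=0.03)
        assert np.allclose(props.com, analytic.com, atol=1e-9)

    def test_too_coarse_voxels_rejected(self):
        spec = PhantomSpec(
            [Primitive("sphere", (0, 0, 0), (0.2,))], voxel_size=5.0
        )
        with pytest.raises(ValueError, match="coarse"):
            make_phantom(spec, margin=0.0)


class TestRandomRigidTransform:
    def test_identity_transform_reproduces_volume(self):
        spec = metatarsal_phantom(voxel_size=0.8)
        vol0, mask0, _ = make_phantom(spec)
        moved = spec.transformed(np.eye(3), np.zeros(3))
        vol1, mask1, _ = make_phantom(moved)
        assert np.array_equal(mask0.mask, mask1.mask)

    def test_lattice_preserving_rotation_is_exact(self):
        # 90 degrees about z maps the cuboid onto itself with swapped axes
        spec = PhantomSpec(
            [Primitive("cuboid", (0, 0, 0), (4.0, 7.0, 11.0))], voxel_size=0.5
        )
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        vol0, mask0, _ = make_phantom(spec)
        vol1, mask1, _ = make_phantom(spec.transformed(R, np.zeros(3)))
        assert mask1.mask.shape == tuple(np.array(mask0.mask.shape)[[1, 0, 2]])
        assert mask0.voxel_count == mask1.voxel_count
        props0 = inf.mass_properties(vol0, mask0)
        props1 = inf.mass_properties(vol1, mask1)
        assert np.allclose(
            props0.principal_moments, props1.principal_moments, rtol=1e-12
        )

    def test_seeded_and_reproducible(self):
        spec = metatarsal_phantom(voxel_size=0.8)
        _, mask_a, (Ra, ta) = random_rigid_transform(spec, seed=5)
        _, mask_b, (Rb, tb) = random_rigid_transform(spec, seed=5)
        assert np.array_equal(Ra, Rb) and np.array_equal(ta, tb)
        assert np.array_equal(mask_a.mask, mask_b.mask)
        assert np.allclose(Ra @ Ra.T, np.eye(3)) and np.linalg.det(Ra) > 0


class TestSimulateCohort:
    def test_deterministic_for_fixed_seed(self):
        spec = cohort_spec_from_reference("left", 3)
        a = simulate_cohort(spec, seed=7)
        b = simulate_cohort(spec, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_large_sample_means_match_spec(self):
        spec = cohort_spec_from_reference("left", 1, n_male=20_000, n_female=20_000,
                                          clip=False)
        df = simulate_cohort(spec, seed=0)
        for v in ("sa_v", "density"):  # unclipped, un-renormalized variables
            for sex in ("male", "female"):
                st = ref.COHORT_STATS[("left", 1)][v][sex]
                got = df.loc[df.sex == sex, v].mean()
                se = st.sd / np.sqrt(20_000)
                assert abs(got - st.mean) < 4 * se, (v, sex)

    def test_triplets_renormalized(self, left_mt3_cohort):
        lin = left_mt3_cohort[["Ln", "Wn", "Hn"]].sum(axis=1)
        rot = left_mt3_cohort[["pmi_x", "pmi_y", "pmi_z"]].sum(axis=1)
        assert np.allclose(lin, 1.0, atol=1e-12)
        assert np.allclose(rot, 1.0, atol=1e-12)

    def test_clipping_respects_printed_ranges(self):
        spec = cohort_spec_from_reference("right", 2, n_male=500, n_female=500)
        df = simulate_cohort(spec, seed=3)
        for sex in ("male", "female"):
            st = ref.COHORT_STATS[("right", 2)]["sa_v"][sex]
            vals = df.loc[df.sex == sex, "sa_v"]
            assert vals.min() >= st.min - 1e-12
            assert vals.max() <= st.max + 1e-12

    def test_sdi_of_simulated_sa_v_matches_published_band(self):
        from osteoinertia.dimorphism import sdi_result

        spec = cohort_spec_from_reference("left", 3)
        values = [
            sdi_result(simulate_cohort(spec, seed=s), "sa_v").sdi
            for s in range(100)
        ]
        # published left 3rd SA:V SDI is -7.656; n=30+30 sampling noise
        assert np.mean(np.abs(np.array(values) + 7.656) < 1.5) >= 0.95

    def test_infeasible_bounds_rejected(self):
        stats = {
            v: {s: ref.SummaryStat(0.5, 0.1, 0.4, 0.6) for s in ("male", "female")}
            for v in ref.VARIABLES
        }
        stats["sa_v"] = {
            s: ref.SummaryStat(0.5, 0.1, 0.7, 0.6) for s in ("male", "female")
        }
        with pytest.raises(ValueError, match="infeasible"):
            CohortSpec(stats=stats)

    def test_covariates_present_with_plausible_pooled_stats(self):
        spec = cohort_spec_from_reference("left", 3, n_male=2000, n_female=2000)
        df = simulate_cohort(spec, seed=4)
        assert abs(df["height_cm"].mean() - 170.9) < 1.0
        assert abs(df["weight_kg"].mean() - 62.5) < 1.0
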