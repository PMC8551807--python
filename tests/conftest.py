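"""Shared fixtures: coarse phantoms and simulated cohorts."""

import pytest
from hypothesis import settings

from osteoinertia.synthetic import (
    PhantomSpec,
    Primitive,
    cohort_spec_from_reference,
    make_phantom,
    simulate_cohort,
)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    """Solid ellipsoid, semi-axes (30, 10, 8) mm, gray 1638.4 (d = 1.6),
    voxelized at 0.4 mm. Returns (volume, mask, analytic properties)."""
    spec = PhantomSpec(
        [Primitive("ellipsoid", (0.0, 0.0, 0.0), (30.0, 10.0, 8.0), gray=1638.4)],
        voxel_size=0.4,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def cuboid_phantom():
    """Nearly-cubic cuboid (distinct moments), 0.25 mm voxels.

    The 0.25 mm grid keeps the three half-extents distinct after
    center-inclusion quantization (at 0.5 mm two of them would collapse
    onto the same voxel count and degenerate the frame).
    """
    spec = PhantomSpec(
        [Primitive("cuboid", (0.0, 0.0, 0.0), (5.0, 5.2, 5.4))], voxel_size=0.25
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def sphere_phantom():
    spec = PhantomSpec(
        [Primitive("sphere", (0.0, 0.0, 0.0), (10.0,))], voxel_size=0.25
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def left_mt3_cohort():
    """Simulated 30 + 30 cohort from the left third-metatarsal summary."""
    return simulate_cohort(cohort_spec_from_reference("left", 3), seed=1)
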