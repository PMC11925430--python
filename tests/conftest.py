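import numpy as np
import pytest

from cranial_iip.calvaria_metrics import (
    build_location_grid,
    compute_maps,
    label_bones,
    segment_calvaria,
)
from cranial_iip.synthetic_data import (
    PhantomSpec,
    default_cohort_design,
    generate_skull_phantom,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_sphere():
    """Noiseless spherical shell, inner 27 / outer 30 mm, 1 mm voxels."""
    spec = PhantomSpec(
        outer_radii=(30.0, 30.0, 30.0),
        thickness_field=3.0,
        density_field=800.0,
        suture_gaps=[],
        blur_fwhm=0.0,
        noise_sd=0.0,
        spacing=(1.0, 1.0, 1.0),
        n_locations=642,
    )
    vol, truth = generate_skull_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def small_sphere_quantified(small_sphere):
    _, vol, _ = small_sphere
    cmask = label_bones(segment_calvaria(vol), suture_bands=[])
    grid = build_location_grid(cmask, 642)
    maps = compute_maps(vol, cmask, grid)
    return vol, cmask, grid, maps


@pytest.fixture(scope="session")
def noisy_cohort():
    """Scaled-down study cohort with the default group effects and noise."""
    design = default_cohort_design(
        n_per_group={
            "normative": 250,
            "IIP": 48,
            "MC": 40,
            "SC": 60,
            "UCC": 40,
            "BCC": 20,
            "AS": 20,
        },
        rng_seed=123,
    )
    return design, simulate_cohort(design)


@pytest.fixture(scope="session")
def noiseless_cohort():
    design = default_cohort_design(
        n_per_group={g: 12 for g in ("normative", "IIP", "MC", "SC", "UCC", "BCC", "AS")},
        noise_sd={"thickness": 0.0, "density": 0.0},
        rng_seed=7,
    )
    return design, simulate_cohort(design)
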