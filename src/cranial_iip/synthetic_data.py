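"""Synthetic skull phantoms and simulated multi-group cohorts.

Real presurgical CT datasets of this kind are not publicly deposited, so
every downstream stage is exercised against two synthetic sources with
exact ground truth:

* **Skull phantoms** — ellipsoidal bone shells rasterized onto a voxel grid
  in Hounsfield units, with direction-dependent analytic thickness and
  density fields, suture gaps at canonical positions, optional Gaussian
  partial-volume blur and additive HU noise.  Ground-truth thickness,
  density and bone labels are evaluated analytically on the standardized
  location grid before any degradation.

* **Simulated cohorts** — per-subject regional thickness/density summaries
  drawn from the 10-term normative regression (intercept, age, sex, voxel
  volume, six mutually exclusive diagnostic-group indicators) with i.i.d.
  Gaussian residuals, for the groups normative, IIP, MC, SC, UCC, BCC, AS.

The default cohort design mirrors the study conditions: group sizes and
covariate distributions follow the published dataset composition, and the
default group effects are of the published magnitude (thickness +0.3 to
+0.6 mm, density -90 to -260 HU relative to normative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import geometry
from .geometry import LABEL_NAMES, SutureBand, canonical_sutures, icosphere_directions
from .normative_model import (
    COEF_NAMES,
    GROUPS,
    INDICATOR_GROUPS,
    MEASURES,
    N_COEF,
    SubjectRecord,
)
from .volume_io import Volume

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: direction-dependent scalar field: (N, 3) unit dirs -> (N,) values
SurfaceField = Callable[[np.ndarray], np.ndarray]


class PhantomParameterError(ValueError):
    """Invalid phantom specification."""


def constant_field(value: float) -> SurfaceField:
    """A surface field that is the same everywhere."""

    def f(dirs: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(dirs).shape[0], float(value))

    return f


def lateral_step_field(left_value: float, right_value: float) -> SurfaceField:
    """Piecewise-constant field: one value on the left (y>0), one on the right."""

    def f(dirs: np.ndarray) -> np.ndarray:
        dirs = np.asarray(dirs)
        return np.where(dirs[:, 1] > 0, float(left_value), float(right_value))

    return f


def _as_field(value: float | SurfaceField) -> SurfaceField:
    if callable(value):
        return value
    return constant_field(float(value))


@dataclass
class PhantomSpec:
    """Analytic description of an ellipsoidal-shell skull phantom.

    The outer surface is the ellipsoid with semi-axes ``outer_radii`` (mm);
    the bone occupies the radial band between the outer surface and
    ``thickness_field`` mm inside it, measured along rays from the centre.
    ``density_field`` gives bone HU per surface direction.  ``suture_gaps``
    carve great-circle bands of non-bone tissue through the shell.
    """

    outer_radii: tuple[float, float, float] = (80.0, 70.0, 65.0)
    thickness_field: float | SurfaceField = 3.0
    density_field: float | SurfaceField = 800.0
    suture_gaps: Sequence[SutureBand] = field(default_factory=canonical_sutures)
    background_hu: float = -1000.0
    blur_fwhm: float = 0.0
    noise_sd: float = 0.0
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.5)
    rng_seed: int = 0
    n_locations: int = 2562
    allow_degenerate: bool = False

    def validate(self) -> None:
        if any(r <= 0 for r in self.outer_radii):
            raise PhantomParameterError(f"non-positive outer radii {self.outer_radii}")
        if any(s <= 0 for s in self.spacing):
            raise PhantomParameterError(f"non-positive spacing {self.spacing}")
        if self.blur_fwhm < 0 or self.noise_sd < 0:
            raise PhantomParameterError("blur_fwhm and noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Analytic per-location truth on the standardized direction grid."""

    directions: np.ndarray  # (N, 3) unit vectors
    thickness_map: np.ndarray  # mm
    density_map: np.ndarray  # HU
    bone_label_map: np.ndarray  # geometry label codes (incl. suture)

    def to_frame(self) -> pd.DataFrame:
        az, el = geometry.azimuth_elevation(self.directions)
        return pd.DataFrame(
            {
                "location_id": np.arange(len(self.directions)),
                "azimuth_deg": az,
                "elevation_deg": el,
                "bone_label": [LABEL_NAMES[int(c)] for c in self.bone_label_map],
                "thickness_mm": self.thickness_map,
                "density_hu": self.density_map,
            }
        )


def _ellipsoid_radius(dirs: np.ndarray, radii: Sequence[float]) -> np.ndarray:
    """Distance from the centre to the ellipsoid surface along each direction."""
    d = np.asarray(dirs, dtype=float)
    r = np.asarray(radii, dtype=float)
    s = np.sum((d / r) ** 2, axis=-1)
    with np.errstate(divide="ignore"):
        return np.where(s > 0, 1.0 / np.sqrt(np.maximum(s, 1e-300)), 0.0)


def generate_skull_phantom(spec: PhantomSpec) -> tuple[Volume, GroundTruth]:
    """Rasterize a phantom spec to a HU volume plus analytic ground truth.

    Rasterization is voxel-centre based: a voxel is bone when its centre
    lies inside the shell band of its direction.  Blur and noise are applied
    after rasterization; the ground truth is evaluated before either.
    """
    spec.validate()
    thickness = _as_field(spec.thickness_field)
    density = _as_field(spec.density_field)
    mean_radius = float(np.mean(spec.outer_radii))

    # ground truth on the standardized direction grid, pre-degradation
    dirs = icosphere_directions(spec.n_locations)
    gt_thickness = np.asarray(thickness(dirs), dtype=float)
    gt_density = np.asarray(density(dirs), dtype=float)
    if np.any(gt_thickness < 0):
        raise PhantomParameterError("thickness_field must be non-negative")
    if not spec.allow_degenerate and np.any(gt_thickness <= 0):
        raise PhantomParameterError(
            "thickness_field must be strictly positive "
            "(set allow_degenerate=True for degenerate test cases)"
        )
    gt_labels = geometry.label_directions(
        dirs, list(spec.suture_gaps), radius_mm=mean_radius
    )
    truth = GroundTruth(
        directions=dirs,
        thickness_map=gt_thickness,
        density_map=gt_density,
        bone_label_map=gt_labels,
    )

    # voxel grid centred on the phantom, padded for blur support
    pad = 6.0 + 3.0 * spec.blur_fwhm
    half = np.asarray(spec.outer_radii) + pad
    sx, sy, sz = spec.spacing
    n = [2 * int(np.ceil(h / s)) + 1 for h, s in zip(half, (sx, sy, sz))]
    coords = [
        (np.arange(n[i]) - (n[i] - 1) / 2.0) * spec.spacing[i] for i in range(3)
    ]
    origin = tuple(float(c[0]) for c in coords)

    values = np.full(tuple(n), spec.background_hu, dtype=np.float32)
    x = coords[0][:, None]
    y = coords[1][None, :]
    chunk = max(1, int(2e6 // (n[0] * n[1])))
    for z0 in range(0, n[2], chunk):
        z = coords[2][z0 : z0 + chunk]
        X = np.broadcast_to(x[:, :, None], (n[0], n[1], len(z)))
        Y = np.broadcast_to(y[:, :, None], (n[0], n[1], len(z)))
        Z = np.broadcast_to(z[None, None, :], (n[0], n[1], len(z)))
        r = np.sqrt(X * X + Y * Y + Z * Z)
        r_safe = np.maximum(r, 1e-9)
        u = np.stack([X / r_safe, Y / r_safe, Z / r_safe], axis=-1)
        flat = u.reshape(-1, 3)
        r_out = _ellipsoid_radius(flat, spec.outer_radii).reshape(r.shape)
        th = np.asarray(thickness(flat), dtype=float).reshape(r.shape)
        shell = (r <= r_out) & (r > r_out - th) & (r > 1e-6)
        if not np.any(shell):
            continue
        hu = np.asarray(density(flat), dtype=float).reshape(r.shape)
        slab = np.full(r.shape, spec.background_hu, dtype=np.float32)
        slab[shell] = hu[shell]
        for band in spec.suture_gaps:
            gap = shell & band.contains(flat, mean_radius).reshape(r.shape)
            slab[gap] = band.gap_hu
        values[:, :, z0 : z0 + chunk] = slab

    if spec.blur_fwhm > 0:
        sigma_vox = [
            spec.blur_fwhm * _FWHM_TO_SIGMA / s for s in spec.spacing
        ]
        values = gaussian_filter(values, sigma=sigma_vox, mode="nearest")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape).astype(
            np.float32
        )

    vol = Volume(values=values, spacing=spec.spacing, origin=origin)
    return vol, truth


# ---------------------------------------------------------------------------
# cohort simulation

class CohortDesignError(ValueError):
    """Invalid cohort design."""


#: regions simulated by the default design: five bones plus the calvarial mean
DEFAULT_REGIONS = (
    "frontal_L",
    "frontal_R",
    "parietal_L",
    "parietal_R",
    "occipital",
    "global",
)


@dataclass
class CohortDesign:
    """Statistical recipe for a simulated cohort.

    ``true_betas`` maps ``(region, measure)`` to the 10-vector of regression
    coefficients in the order (intercept, age, sex, voxel_volume, IIP, MC,
    SC, UCC, BCC, AS).  ``age_distribution`` and
    ``voxel_volume_distribution`` give per-group (mean, SD); ``sex_ratio``
    is the per-group fraction male (a scalar applies to all groups).
    ``noise_sd`` is the residual SD per measure.
    """

    n_per_group: Mapping[str, int]
    age_distribution: Mapping[str, tuple[float, float]]
    sex_ratio: Mapping[str, float] | float
    voxel_volume_distribution: Mapping[str, tuple[float, float]] | tuple[float, float]
    true_betas: Mapping[tuple[str, str], np.ndarray]
    noise_sd: Mapping[str, float]
    rng_seed: int = 0

    def validate(self) -> None:
        for g, cnt in self.n_per_group.items():
            if g not in GROUPS:
                raise CohortDesignError(f"unknown group {g!r}")
            if cnt < 0:
                raise CohortDesignError(f"negative count for group {g!r}")
        if sum(self.n_per_group.values()) == 0:
            raise CohortDesignError("empty design: all group counts are zero")
        for key, beta in self.true_betas.items():
            if np.asarray(beta).shape != (N_COEF,):
                raise CohortDesignError(
                    f"true_betas[{key}] must have length {N_COEF}"
                )

    def sex_ratio_for(self, group: str) -> float:
        if isinstance(self.sex_ratio, Mapping):
            return float(self.sex_ratio[group])
        return float(self.sex_ratio)

    def voxel_volume_for(self, group: str) -> tuple[float, float]:
        if isinstance(self.voxel_volume_distribution, Mapping):
            return tuple(self.voxel_volume_distribution[group])  # type: ignore[return-value]
        return tuple(self.voxel_volume_distribution)  # type: ignore[return-value]


def simulate_cohort(design: CohortDesign) -> list[SubjectRecord]:
    """Draw a cohort of :class:`SubjectRecord` from a design.

    Each subject's regional measurements are the linear predictor of the
    10-term normative model plus i.i.d. Gaussian noise.  Group indicators
    are one-hot by construction; the draw is reproducible under
    ``design.rng_seed``.
    """
    design.validate()
    rng = np.random.default_rng(design.rng_seed)
    keys = list(design.true_betas)
    betas = {k: np.asarray(design.true_betas[k], dtype=float) for k in keys}
    cohort: list[SubjectRecord] = []
    for group in GROUPS:  # fixed order for reproducibility
        n = int(design.n_per_group.get(group, 0))
        if n == 0:
            continue
        age_mu, age_sd = design.age_distribution[group]
        vv_mu, vv_sd = design.voxel_volume_for(group)
        p_male = design.sex_ratio_for(group)
        for i in range(n):
            age = max(0.0, float(rng.normal(age_mu, age_sd)))
            sex = int(rng.random() < p_male)
            vv = max(1e-3, float(rng.normal(vv_mu, vv_sd)))
            rec = SubjectRecord(
                subject_id=f"{group}_{i:04d}",
                age=age,
                sex=sex,
                voxel_volume=vv,
                group=group,
            )
            x = rec.covariate_row
            for (region, measure), beta in betas.items():
                noise = design.noise_sd.get(measure, 0.0)
                y = float(beta @ x)
                if noise > 0:
                    y += float(rng.normal(0.0, noise))
                rec.measurements[(region, measure)] = y
            cohort.append(rec)
    return cohort


# ---------------------------------------------------------------------------
# default study-condition design

# group effects relative to normative, per region, order (IIP, MC, SC, UCC, BCC, AS);
# UCC frontal/parietal effects are side-specific (fused side = left by default).
_THICKNESS_EFFECTS = {
    "frontal_L": (0.06, 0.51, 0.47, 0.37, 0.61, 0.39),
    "frontal_R": (0.06, 0.51, 0.47, 0.49, 0.61, 0.39),
    "parietal_L": (-0.04, 0.37, 0.37, 0.26, 0.40, 0.24),
    "parietal_R": (-0.04, 0.37, 0.37, 0.40, 0.40, 0.24),
    "occipital": (0.18, 0.35, 0.35, 0.31, 0.51, 0.33),
    "global": (0.04, 0.41, 0.40, 0.37, 0.50, 0.31),
}
_DENSITY_EFFECTS = {
    "frontal_L": (-174.65, -155.80, -140.24, -143.80, -161.63, -255.63),
    "frontal_R": (-174.65, -155.80, -140.24, -138.67, -161.63, -255.63),
    "parietal_L": (-175.35, -134.10, -165.51, -141.59, -125.55, -197.99),
    "parietal_R": (-175.35, -134.10, -165.51, -135.94, -125.55, -197.99),
    "occipital": (-120.31, -94.44, -122.30, -90.68, -95.02, -109.07),
    "global": (-163.73, -132.92, -149.60, -130.96, -131.84, -196.47),
}

# normative baselines (intercept, age, sex, voxel-volume terms); see docs/methods.md
_THICKNESS_BASE = {
    "frontal_L": 2.6,
    "frontal_R": 2.6,
    "parietal_L": 2.4,
    "parietal_R": 2.4,
    "occipital": 2.8,
    "global": 2.6,
}
_DENSITY_BASE = {
    "frontal_L": 650.0,
    "frontal_R": 650.0,
    "parietal_L": 620.0,
    "parietal_R": 620.0,
    "occipital": 700.0,
    "global": 650.0,
}
_THICKNESS_COVARIATES = (0.35, 0.05, -0.5)  # per year, male, per mm^3
_DENSITY_COVARIATES = (55.0, 10.0, -400.0)

#: residual SDs consistent with the published standard errors
DEFAULT_NOISE_SD = {"thickness": 0.4, "density": 140.0}

#: published per-dataset sample sizes (AS counted per scan: 14 patients, 19 images)
STUDY_GROUP_SIZES = {
    "normative": 1018,
    "IIP": 48,
    "MC": 79,
    "SC": 242,
    "UCC": 63,
    "BCC": 19,
    "AS": 19,
}

STUDY_AGE_YEARS = {
    "normative": (3.08, 3.02),
    "IIP": (4.23, 3.13),
    "MC": (0.39, 0.33),
    "SC": (0.39, 0.33),
    "UCC": (0.39, 0.33),
    "BCC": (0.39, 0.33),
    "AS": (0.28, 0.30),
}

STUDY_SEX_RATIO = {
    "normative": 0.5295,
    "IIP": 0.4792,
    "MC": 0.66,
    "SC": 0.66,
    "UCC": 0.66,
    "BCC": 0.66,
    "AS": 0.4211,
}

STUDY_VOXEL_VOLUME_MM3 = {
    "normative": (0.105, 0.057),
    "IIP": (0.095, 0.030),
    "MC": (0.087, 0.045),
    "SC": (0.087, 0.045),
    "UCC": (0.087, 0.045),
    "BCC": (0.087, 0.045),
    "AS": (0.060, 0.017),
}


def default_true_betas() -> dict[tuple[str, str], np.ndarray]:
    """The default coefficient table: study-magnitude group effects over
    realistic pediatric baselines."""
    betas: dict[tuple[str, str], np.ndarray] = {}
    for region in DEFAULT_REGIONS:
        betas[(region, "thickness")] = np.concatenate(
            [
                [_THICKNESS_BASE[region]],
                _THICKNESS_COVARIATES,
                _THICKNESS_EFFECTS[region],
            ]
        )
        betas[(region, "density")] = np.concatenate(
            [[_DENSITY_BASE[region]], _DENSITY_COVARIATES, _DENSITY_EFFECTS[region]]
        )
    return betas


def default_cohort_design(
    n_per_group: Mapping[str, int] | None = None,
    rng_seed: int = 0,
    noise_sd: Mapping[str, float] | None = None,
) -> CohortDesign:
    """The study-condition cohort design (published group sizes by default)."""
    return CohortDesign(
        n_per_group=dict(n_per_group if n_per_group is not None else STUDY_GROUP_SIZES),
        age_distribution=dict(STUDY_AGE_YEARS),
        sex_ratio=dict(STUDY_SEX_RATIO),
        voxel_volume_distribution=dict(STUDY_VOXEL_VOLUME_MM3),
        true_betas=default_true_betas(),
        noise_sd=dict(noise_sd if noise_sd is not None else DEFAULT_NOISE_SD),
        rng_seed=rng_seed,
    )


def cohort_composition(cohort: list[SubjectRecord]) -> pd.DataFrame:
    """Counts and percentages per group, plus the share of each nonsyndromic
    phenotype among single-suture nonsyndromic subjects."""
    df = pd.DataFrame({"group": [r.group for r in cohort]})
    counts = df["group"].value_counts().reindex(list(GROUPS), fill_value=0)
    total = counts.sum()
    nscs = ("MC", "SC", "UCC", "BCC")
    n_nscs = int(counts[list(nscs)].sum())
    out = pd.DataFrame(
        {
            "group": counts.index,
            "n": counts.values,
            "pct_of_cohort": 100.0 * counts.values / total,
        }
    )
    out["pct_of_nonsyndromic"] = [
        100.0 * counts[g] / n_nscs if g in nscs and n_nscs else np.nan
        for g in counts.index
    ]
    return out


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.to_frame().to_csv(path, index=False)
    return path
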