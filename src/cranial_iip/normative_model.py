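"""Covariate-adjusted normative regression of calvarial measurements.

Each subject contributes per-region thickness (mm) and density (HU)
summaries together with age (years), sex (1 male / 0 female), the original
acquisition voxel volume (mm^3) and a diagnostic group.  For every region
and measure the model is the 10-term linear regression

    Y = b0 + b1*Age + b2*Sex + b3*V
          + b4*IIP + b5*MC + b6*SC + b7*UCC + b8*BCC + b9*AS + eps,

where the six diagnostic indicators are mutually exclusive and all-zero for
normative subjects.  Adjusted measurements subtract the fitted age, sex and
voxel-volume effects (group effects are retained), and group contrasts are
Welch t tests on the adjusted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: diagnostic groups in design-matrix order; 'normative' is the reference
GROUPS = ("normative", "IIP", "MC", "SC", "UCC", "BCC", "AS")
INDICATOR_GROUPS = GROUPS[1:]
COEF_NAMES = ("intercept", "age", "sex", "voxel_volume") + INDICATOR_GROUPS
N_COEF = len(COEF_NAMES)

MEASURES = ("thickness", "density")


class CohortError(ValueError):
    """Invalid cohort for the requested operation."""


@dataclass
class SubjectRecord:
    """One subject (one scan): covariates, group and regional summaries.

    ``measurements`` maps ``(region, measure)`` — e.g. ``("frontal_L",
    "density")`` or ``("global", "thickness")`` — to a scalar value.
    """

    subject_id: str
    age: float
    sex: int
    voxel_volume: float
    group: str
    measurements: dict[tuple[str, str], float] = field(default_factory=dict)
    patient_id: str | None = None  # shared across repeat scans

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.age < 0:
            raise CohortError(f"negative age {self.age} for {self.subject_id}")
        if self.voxel_volume <= 0:
            raise CohortError(
                f"non-positive voxel volume {self.voxel_volume} for {self.subject_id}"
            )
        self.sex = int(self.sex)
        if self.patient_id is None:
            self.patient_id = self.subject_id

    @property
    def indicators(self) -> np.ndarray:
        """One-hot diagnostic indicators in design order (all zero = normative)."""
        out = np.zeros(len(INDICATOR_GROUPS))
        if self.group != "normative":
            out[INDICATOR_GROUPS.index(self.group)] = 1.0
        return out

    @property
    def covariate_row(self) -> np.ndarray:
        """Design-matrix row [1, age, sex, V, IIP, MC, SC, UCC, BCC, AS]."""
        return np.concatenate(
            [[1.0, self.age, float(self.sex), self.voxel_volume], self.indicators]
        )


@dataclass
class NormativeFit:
    """Fitted coefficients for one (region, measure) regression."""

    region: str
    measure: str
    coef: np.ndarray
    se: np.ndarray
    resid_sd: float
    n: int
    coef_names: tuple[str, ...] = COEF_NAMES

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.coef.shape != (N_COEF,):
            raise ValueError(f"coefficient vector must have length {N_COEF}")

    def group_effect(self, group: str) -> float:
        """Fitted effect of a diagnostic group relative to normative."""
        return float(self.coef[COEF_NAMES.index(group)])


@dataclass
class GroupContrast:
    """A Table-style pairwise contrast of adjusted values."""

    region: str
    measure: str
    pair: str  # e.g. "MC versus IIP"
    mean_difference: float
    sd: float  # standard error of the mean difference
    p_value: float
    n_a: int
    n_b: int


def design_matrix(cohort: list[SubjectRecord]) -> np.ndarray:
    return np.vstack([r.covariate_row for r in cohort])


def response_vector(
    cohort: list[SubjectRecord], region: str, measure: str
) -> np.ndarray:
    return np.array(
        [r.measurements.get((region, measure), np.nan) for r in cohort], dtype=float
    )


def fit_normative_regression(
    cohort: list[SubjectRecord], region: str, measure: str
) -> NormativeFit:
    """Ordinary-least-squares fit of the 10-term model for one region/measure.

    Subjects missing the measurement are dropped.  Raises
    :class:`CohortError` when fewer than 11 usable subjects remain or the
    design is rank deficient (naming the offending column, e.g. an absent
    diagnostic group).
    """
    X = design_matrix(cohort)
    y = response_vector(cohort, region, measure)
    keep = np.isfinite(y)
    X, y = X[keep], y[keep]
    if len(y) <= 10:
        raise CohortError(
            f"need more than 10 subjects with ({region}, {measure}); got {len(y)}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < N_COEF:
        zero_cols = [COEF_NAMES[j] for j in range(1, N_COEF) if not np.any(X[:, j])]
        detail = (
            f"columns {zero_cols} are all zero (group absent?)"
            if zero_cols
            else "columns are collinear"
        )
        raise CohortError(f"design matrix rank {rank} < {N_COEF}: {detail}")
    res = sm.OLS(y, X).fit()
    return NormativeFit(
        region=region,
        measure=measure,
        coef=np.asarray(res.params),
        se=np.asarray(res.bse),
        resid_sd=float(np.sqrt(res.scale)),
        n=int(res.nobs),
    )


def adjust_measurement(record: SubjectRecord, fit: NormativeFit) -> float:
    """Observed value minus the fitted age, sex and voxel-volume effects.

    Group effects are deliberately retained; a missing measurement yields
    NaN.
    """
    obs = record.measurements.get((fit.region, fit.measure), np.nan)
    if not np.isfinite(obs):
        return float("nan")
    b1, b2, b3 = fit.coef[1], fit.coef[2], fit.coef[3]
    return float(obs - (b1 * record.age + b2 * record.sex + b3 * record.voxel_volume))


def adjust_cohort(cohort: list[SubjectRecord], fit: NormativeFit) -> np.ndarray:
    """Vector of adjusted values for a cohort (NaN where missing)."""
    return np.array([adjust_measurement(r, fit) for r in cohort])


def contrast_groups(
    cohort: list[SubjectRecord],
    fit: NormativeFit,
    group_a: str,
    group_b: str,
) -> GroupContrast:
    """Welch t-test contrast "A versus B" on adjusted values.

    The mean difference is mean(A) - mean(B); the reported SD is the
    standard error of that difference, sqrt(var_a/n_a + var_b/n_b).
    """
    adjusted = adjust_cohort(cohort, fit)
    vals: dict[str, np.ndarray] = {}
    for g in (group_a, group_b):
        if g not in GROUPS:
            raise CohortError(f"unknown group {g!r}")
        v = adjusted[[r.group == g for r in cohort]]
        v = v[np.isfinite(v)]
        if len(v) < 2:
            raise CohortError(f"group {g!r} has fewer than 2 usable subjects")
        vals[g] = v
    a, b = vals[group_a], vals[group_b]
    mean_diff = float(a.mean() - b.mean())
    se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(p):  # both groups constant and equal
        p = 1.0 if np.isclose(mean_diff, 0.0) else 0.0
    return GroupContrast(
        region=fit.region,
        measure=fit.measure,
        pair=f"{group_a} versus {group_b}",
        mean_difference=mean_diff,
        sd=se,
        p_value=float(p),
        n_a=len(a),
        n_b=len(b),
    )


#: pairwise contrasts reported in the standard group-difference tables
DEFAULT_PAIRS = (
    ("IIP", "normative"),
    ("MC", "normative"),
    ("SC", "normative"),
    ("BCC", "normative"),
    ("AS", "normative"),
    ("MC", "IIP"),
    ("SC", "IIP"),
    ("BCC", "IIP"),
    ("AS", "IIP"),
)

UCC_PAIRS = (("UCC", "normative"), ("UCC", "IIP"))


def with_merged_sides(cohort: list[SubjectRecord]) -> list[SubjectRecord]:
    """Add merged frontal/parietal measurements (mean of L and R) in place.

    Returns the same list for chaining; records lacking one side keep only
    what they have.
    """
    for rec in cohort:
        for bone in ("frontal", "parietal"):
            for measure in MEASURES:
                left = rec.measurements.get((f"{bone}_L", measure))
                right = rec.measurements.get((f"{bone}_R", measure))
                if left is not None and right is not None:
                    rec.measurements.setdefault(
                        (bone, measure), 0.5 * (left + right)
                    )
    return cohort


def contrast_table(
    cohort: list[SubjectRecord],
    regions: tuple[str, ...] = ("frontal", "parietal", "occipital", "global"),
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
    measures: tuple[str, ...] = MEASURES,
) -> pd.DataFrame:
    """Group-difference table (region x pair x measure) on adjusted values."""
    rows = []
    for region in regions:
        for measure in measures:
            fit = fit_normative_regression(cohort, region, measure)
            for ga, gb in pairs:
                c = contrast_groups(cohort, fit, ga, gb)
                rows.append(
                    {
                        "region": region,
                        "measure": measure,
                        "pair": c.pair,
                        "mean_difference": c.mean_difference,
                        "sd": c.sd,
                        "p_value": c.p_value,
                        "n_a": c.n_a,
                        "n_b": c.n_b,
                    }
                )
    return pd.DataFrame(rows)


def ucc_side_table(
    cohort: list[SubjectRecord],
    fused_side: str = "left",
    measures: tuple[str, ...] = MEASURES,
) -> pd.DataFrame:
    """Side-resolved UCC contrasts (fused vs open coronal suture side).

    Frontal and parietal bones are reported separately on the fused and the
    open side; the occipital bone and the calvarial average are reported
    once.
    """
    if fused_side not in ("left", "right"):
        raise CohortError(f"fused_side must be 'left' or 'right', got {fused_side!r}")
    f, o = ("L", "R") if fused_side == "left" else ("R", "L")
    region_map = {
        "frontal_fused_side": f"frontal_{f}",
        "frontal_open_side": f"frontal_{o}",
        "parietal_fused_side": f"parietal_{f}",
        "parietal_open_side": f"parietal_{o}",
        "occipital": "occipital",
        "global": "global",
    }
    rows = []
    for label, region in region_map.items():
        for measure in measures:
            fit = fit_normative_regression(cohort, region, measure)
            for ga, gb in UCC_PAIRS:
                c = contrast_groups(cohort, fit, ga, gb)
                rows.append(
                    {
                        "region": label,
                        "measure": measure,
                        "pair": c.pair,
                        "mean_difference": c.mean_difference,
                        "sd": c.sd,
                        "p_value": c.p_value,
                        "n_a": c.n_a,
                        "n_b": c.n_b,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort (de)serialization

def cohort_to_frame(cohort: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten a cohort to one row per subject, measurements as
    ``{measure}__{region}`` columns."""
    rows = []
    for r in cohort:
        row = {
            "subject_id": r.subject_id,
            "patient_id": r.patient_id,
            "group": r.group,
            "age": r.age,
            "sex": r.sex,
            "voxel_volume": r.voxel_volume,
        }
        for (region, measure), val in r.measurements.items():
            row[f"{measure}__{region}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(df: pd.DataFrame) -> list[SubjectRecord]:
    cohort = []
    meas_cols = [c for c in df.columns if "__" in c]
    for _, row in df.iterrows():
        measurements = {}
        for col in meas_cols:
            measure, region = col.split("__", 1)
            val = row[col]
            if pd.notna(val):
                measurements[(region, measure)] = float(val)
        cohort.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                patient_id=str(row.get("patient_id", row["subject_id"])),
                age=float(row["age"]),
                sex=int(row["sex"]),
                voxel_volume=float(row["voxel_volume"]),
                group=str(row["group"]),
                measurements=measurements,
            )
        )
    return cohort


def write_cohort(cohort: list[SubjectRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort_to_frame(cohort).to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    return frame_to_cohort(pd.read_csv(path))
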