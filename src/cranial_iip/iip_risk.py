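"""Probabilistic screening for cranial bone signs of chronic IIP.

A logistic regression on covariate-adjusted bone densities (whole-calvaria
mean plus the five bones) separates normative subjects from patients with
confirmed chronic intracranial hypertension.  Two operating points are kept
from cross-validated scores: the Youden-index threshold (maximizing
sensitivity + specificity - 1) and the smallest threshold reaching at least
95% specificity, intended for screening.  The fitted model then scores
craniosynostosis cohorts; per-group prevalence is the fraction of subjects
whose risk probability reaches a threshold.  Distribution comparisons use
two-sided Mann-Whitney U tests with Bonferroni correction, and the
risk-age association uses Spearman rank correlation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .normative_model import NormativeFit, SubjectRecord, adjust_measurement

logger = logging.getLogger(__name__)

#: adjusted-density features used by the classifier
DEFAULT_FEATURE_REGIONS = (
    "global",
    "frontal_L",
    "frontal_R",
    "parietal_L",
    "parietal_R",
    "occipital",
)

# weak L2 by default: keeps separable inputs finite without visibly
# shrinking coefficients on realistic cohorts
DEFAULT_C = 1e4


class RiskModelError(ValueError):
    """Invalid input for risk-model fitting or threshold selection."""


@dataclass
class RiskModel:
    """Fitted logistic IIP classifier with its operating points."""

    feature_names: list[str]
    coef: np.ndarray
    intercept: float
    cv_scheme: str
    roc: pd.DataFrame  # columns threshold, sensitivity, specificity
    yi_threshold: float
    spec95_threshold: float
    cv_scores: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    cv_labels: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        z = X @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "feature_names": list(self.feature_names),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "cv_scheme": self.cv_scheme,
            "yi_threshold": self.yi_threshold,
            "spec95_threshold": self.spec95_threshold,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


@dataclass
class RiskScores:
    """Per-subject IIP risk probabilities with group labels."""

    scores: np.ndarray
    groups: np.ndarray
    subject_ids: np.ndarray | None = None
    patient_ids: np.ndarray | None = None
    ages: np.ndarray | None = None

    def for_group(self, group: str) -> np.ndarray:
        sel = (self.groups == group) & np.isfinite(self.scores)
        return self.scores[sel]


def build_feature_matrix(
    cohort: list[SubjectRecord],
    fits: dict[str, NormativeFit],
    feature_regions: tuple[str, ...] = DEFAULT_FEATURE_REGIONS,
) -> tuple[np.ndarray, list[str]]:
    """Adjusted-density feature matrix (n_subjects x n_regions).

    ``fits`` maps region name to its fitted density regression; rows with a
    missing region value contain NaN there.
    """
    names = [f"adj_density_{r}" for r in feature_regions]
    X = np.empty((len(cohort), len(feature_regions)))
    for j, region in enumerate(feature_regions):
        fit = fits[region]
        if fit.measure != "density":
            raise RiskModelError(f"fit for {region!r} is not a density fit")
        X[:, j] = [adjust_measurement(r, fit) for r in cohort]
    return X, names


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Sensitivity/specificity at every candidate threshold.

    Candidates are the midpoints between consecutive sorted unique scores;
    a subject is called positive when its score is >= the threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise RiskModelError("need at least two distinct scores for a ROC")
    thresholds = 0.5 * (uniq[:-1] + uniq[1:])
    pos = labels.sum()
    neg = (~labels).sum()
    sens = np.array([(scores[labels] >= t).sum() / pos for t in thresholds])
    spec = np.array([(scores[~labels] < t).sum() / neg for t in thresholds])
    return pd.DataFrame(
        {"threshold": thresholds, "sensitivity": sens, "specificity": spec}
    )


def select_thresholds(
    scores: np.ndarray, labels: np.ndarray, min_specificity: float = 0.95
) -> tuple[float, float]:
    """Youden-index and minimum->=95%-specificity thresholds.

    The Youden threshold maximizes sensitivity + specificity - 1 (ties go to
    the smallest threshold); the screening threshold is the smallest
    candidate whose specificity reaches ``min_specificity``.  Raises
    :class:`RiskModelError` when no candidate reaches it.
    """
    roc = roc_points(scores, labels)
    youden = roc["sensitivity"].to_numpy() + roc["specificity"].to_numpy() - 1.0
    yi_threshold = float(roc["threshold"].to_numpy()[int(np.argmax(youden))])
    ok = roc["specificity"].to_numpy() >= min_specificity
    if not np.any(ok):
        raise RiskModelError(
            f"no candidate threshold reaches specificity {min_specificity}"
        )
    spec95_threshold = float(roc["threshold"].to_numpy()[np.argmax(ok)])
    return yi_threshold, spec95_threshold


def fit_iip_classifier(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    C: float = DEFAULT_C,
    cv_folds: int = 10,
    seed: int = 0,
) -> RiskModel:
    """Maximum-likelihood logistic fit with cross-validated operating points.

    ``y`` is 1 for chronic-IIP subjects, 0 for normative.  Out-of-fold
    predicted probabilities (stratified ``cv_folds``-fold, shuffled with
    ``seed``) are retained and used to pick both thresholds, so the
    operating points are not chosen on resubstitution scores.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or len(X) != len(y):
        raise RiskModelError("X must be 2-D with one row per label")
    keep = np.all(np.isfinite(X), axis=1)
    if not np.all(keep):
        logger.warning("dropping %d rows with missing features", (~keep).sum())
        X, y = X[keep], y[keep]
    classes = np.unique(y)
    if len(classes) < 2:
        raise RiskModelError("both classes must be present to fit the classifier")
    if len(y) < 20:
        raise RiskModelError(f"need at least 20 subjects, got {len(y)}")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]

    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-10)
    folds = min(cv_folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_scores = cross_val_predict(clf, X, y, cv=cv, method="predict_proba")[:, 1]
    clf.fit(X, y)
    roc = roc_points(cv_scores, y)
    try:
        yi, spec95 = select_thresholds(cv_scores, y)
    except RiskModelError:
        # small/overlapping samples may leave 95% specificity unreachable on
        # out-of-fold scores; keep the Youden point and flag the screening one
        logger.warning(
            "no cross-validated threshold reaches 95%% specificity; "
            "screening threshold left undefined"
        )
        youden = roc["sensitivity"].to_numpy() + roc["specificity"].to_numpy() - 1.0
        yi = float(roc["threshold"].to_numpy()[int(np.argmax(youden))])
        spec95 = float("nan")
    return RiskModel(
        feature_names=list(feature_names),
        coef=np.asarray(clf.coef_[0]),
        intercept=float(clf.intercept_[0]),
        cv_scheme=f"stratified {folds}-fold, shuffle seed {seed}",
        roc=roc,
        yi_threshold=yi,
        spec95_threshold=spec95,
        cv_scores=cv_scores,
        cv_labels=y,
    )


def score_subjects(
    model: RiskModel,
    cohort: list[SubjectRecord],
    fits: dict[str, NormativeFit],
    feature_regions: tuple[str, ...] = DEFAULT_FEATURE_REGIONS,
) -> RiskScores:
    """Per-subject risk probabilities; missing features give NaN scores."""
    X, _ = build_feature_matrix(cohort, fits, feature_regions)
    scores = np.full(len(cohort), np.nan)
    ok = np.all(np.isfinite(X), axis=1)
    if not np.all(ok):
        logger.warning("%d subjects lack features and were not scored", (~ok).sum())
    scores[ok] = model.predict_proba(X[ok])
    return RiskScores(
        scores=scores,
        groups=np.array([r.group for r in cohort]),
        subject_ids=np.array([r.subject_id for r in cohort]),
        patient_ids=np.array([r.patient_id for r in cohort]),
        ages=np.array([r.age for r in cohort]),
    )


def estimate_prevalence(
    scores: RiskScores,
    threshold: float,
    groups: tuple[str, ...] | None = None,
    per_patient: bool = False,
) -> pd.DataFrame:
    """Percent of each group at or above the risk threshold.

    With ``per_patient=True`` repeat scans of a patient are first reduced to
    their mean score, so prevalence is per patient rather than per scan.
    """
    if groups is None:
        groups = tuple(dict.fromkeys(scores.groups))
    rows = []
    for g in groups:
        sel = (scores.groups == g) & np.isfinite(scores.scores)
        vals = scores.scores[sel]
        if per_patient and scores.patient_ids is not None:
            pats = scores.patient_ids[sel]
            vals = (
                pd.Series(vals).groupby(pd.Series(pats)).mean().to_numpy()
            )
        n = len(vals)
        rows.append(
            {
                "group": g,
                "n": n,
                "prevalence_pct": 100.0 * float((vals >= threshold).sum()) / n
                if n
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def compare_risk_distributions(
    scores: RiskScores,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per group pair, Bonferroni-adjusted.

    The correction multiplier is the number of pairs actually tested and is
    recorded in the output (``m``).
    """
    if pairs is None:
        present = [g for g in dict.fromkeys(scores.groups)]
        pairs = list(combinations(present, 2))
    m = len(pairs)
    rows = []
    for ga, gb in pairs:
        a, b = scores.for_group(ga), scores.for_group(gb)
        if len(a) < 2 or len(b) < 2:
            raise RiskModelError(
                f"groups {ga!r}/{gb!r} need >= 2 observations each"
            )
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "pair": f"{ga} versus {gb}",
                "U": float(res.statistic),
                "p_raw": float(res.pvalue),
                "p_bonferroni": float(min(1.0, m * res.pvalue)),
                "m": m,
                "n_a": len(a),
                "n_b": len(b),
            }
        )
    return pd.DataFrame(rows)


def correlate_risk_age(
    scores: np.ndarray, ages: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation (tie-corrected) between risk and age.

    Returns (rho, p); a constant input makes rho undefined and yields
    (nan, nan) with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    keep = np.isfinite(scores) & np.isfinite(ages)
    scores, ages = scores[keep], ages[keep]
    if len(scores) < 3:
        raise RiskModelError("need at least 3 paired observations")
    if np.ptp(scores) == 0 or np.ptp(ages) == 0:
        warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(scores, ages)
    return float(rho), float(p)
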