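"""Risk classifier, operating-point selection and nonparametric comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cranial_iip.iip_risk import (
    RiskModelError,
    RiskScores,
    compare_risk_distributions,
    correlate_risk_age,
    estimate_prevalence,
    fit_iip_classifier,
    roc_points,
    score_subjects,
    select_thresholds,
)


def _make_scores(scores, groups):
    return RiskScores(scores=np.asarray(scores, float), groups=np.asarray(groups))


# ---------------------------------------------------------------------------
# classifier fitting

def _gaussian_classes(n0, n1, shift, seed, p=3):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0.0, 1.0, (n0, p)), rng.normal(shift, 1.0, (n1, p))]
    )
    y = np.r_[np.zeros(n0, int), np.ones(n1, int)]
    return X, y


def test_separable_features_give_high_cv_auc():
    from sklearn.metrics import roc_auc_score

    X, y = _gaussian_classes(60, 60, shift=8.0, seed=0)
    model = fit_iip_classifier(X, y, seed=1)
    assert roc_auc_score(model.cv_labels, model.cv_scores) > 0.99


def test_permuted_labels_give_chance_level_auc():
    from sklearn.metrics import roc_auc_score

    X, y = _gaussian_classes(100, 100, shift=1.5, seed=2)
    aucs = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        yp = rng.permutation(y)
        model = fit_iip_classifier(X, yp, seed=seed)
        aucs.append(roc_auc_score(model.cv_labels, model.cv_scores))
    assert 0.4 < np.mean(aucs) < 0.6


def _irls_logistic(X, y, tol=1e-12, max_iter=200):
    """Independent iteratively-reweighted least-squares logistic fit."""
    Xd = np.column_stack([np.ones(len(X)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        grad = Xd.T @ (y - mu)
        H = Xd.T @ (Xd * W[:, None])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def test_coefficients_match_irls_oracle():
    # non-separable 20-point instance; regularization disabled
    X, y = _gaussian_classes(10, 10, shift=1.0, seed=3, p=2)
    model = fit_iip_classifier(X, y, C=1e12, cv_folds=2, seed=0)
    oracle = _irls_logistic(X, y.astype(float))
    assert model.intercept == pytest.approx(oracle[0], abs=1e-6)
    assert np.allclose(model.coef, oracle[1:], atol=1e-6)


def test_single_class_and_tiny_inputs_rejected():
    X = np.random.default_rng(0).normal(size=(30, 2))
    with pytest.raises(RiskModelError):
        fit_iip_classifier(X, np.zeros(30, int))
    with pytest.raises(RiskModelError):
        fit_iip_classifier(X[:10], np.r_[np.zeros(5, int), np.ones(5, int)])


# ---------------------------------------------------------------------------
# threshold selection

def _exhaustive_thresholds(scores, labels, min_spec=0.95):
    """Brute-force evaluation of every candidate threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    uniq = sorted(set(scores))
    cands = [(a + b) / 2.0 for a, b in zip(uniq[:-1], uniq[1:])]
    best_yi, best_t, spec95_t = -np.inf, None, None
    for t in cands:
        tp = sum(1 for s, l in zip(scores, labels) if l and s >= t)
        tn = sum(1 for s, l in zip(scores, labels) if not l and s < t)
        sens = tp / labels.sum()
        spec = tn / (~labels).sum()
        yi = sens + spec - 1.0
        if yi > best_yi:
            best_yi, best_t = yi, t
        if spec95_t is None and spec >= min_spec:
            spec95_t = t
    return best_t, spec95_t


def test_thresholds_match_exhaustive_search():
    rng = np.random.default_rng(4)
    labels = np.r_[np.zeros(12, int), np.ones(8, int)]
    scores = np.clip(rng.normal(0.4, 0.2, 20) + 0.25 * labels, 0, 1)
    yi, spec95 = select_thresholds(scores, labels)
    yi_o, spec95_o = _exhaustive_thresholds(scores, labels)
    assert yi == pytest.approx(yi_o)
    assert spec95 == pytest.approx(spec95_o)


def test_perfectly_separated_scores_hit_both_operating_points():
    scores = np.r_[np.linspace(0.05, 0.3, 10), np.linspace(0.7, 0.95, 10)]
    labels = np.r_[np.zeros(10, int), np.ones(10, int)]
    yi, spec95 = select_thresholds(scores, labels)
    roc = roc_points(scores, labels)
    for t in (yi, spec95):
        row = roc.iloc[(roc["threshold"] - t).abs().argmin()]
        assert row["sensitivity"] == 1.0
        assert row["specificity"] == 1.0


def test_spec95_threshold_meets_its_contract():
    rng = np.random.default_rng(5)
    labels = rng.integers(0, 2, 200)
    scores = np.clip(rng.random(200) + 0.2 * labels, 0, 1.2) / 1.2
    _, spec95 = select_thresholds(scores, labels)
    neg = scores[labels == 0]
    assert (neg < spec95).mean() >= 0.95


def test_unreachable_specificity_raises():
    # every negative shares the top score: no candidate separates them
    scores = np.array([1.0, 1.0, 1.0, 0.2, 0.4, 1.0])
    labels = np.array([0, 0, 0, 1, 1, 1])
    with pytest.raises(RiskModelError, match="specificity"):
        select_thresholds(scores, labels)


# ---------------------------------------------------------------------------
# scoring

def test_scores_lie_in_unit_interval_and_calibrate_at_the_mean():
    X, y = _gaussian_classes(100, 100, shift=1.0, seed=6)
    model = fit_iip_classifier(X, y, seed=0)
    probs = model.predict_proba(X)
    assert np.all((probs >= 0) & (probs <= 1))
    # balanced training data: the feature-mean subject scores near prevalence 0.5
    assert model.predict_proba(X.mean(axis=0)[None, :])[0] == pytest.approx(
        0.5, abs=0.1
    )


def test_lowering_a_negative_weight_feature_raises_the_score():
    X, y = _gaussian_classes(80, 80, shift=-1.5, seed=7)  # class 1 has LOWER values
    model = fit_iip_classifier(X, y, seed=0)
    j = int(np.argmin(model.coef))
    assert model.coef[j] < 0
    base = X.mean(axis=0)
    lowered = base.copy()
    lowered[j] -= 1.0
    assert model.predict_proba(lowered[None, :])[0] > model.predict_proba(base[None, :])[0]


def test_score_subjects_flags_missing_features(noisy_cohort):
    import copy

    from cranial_iip import iip_risk
    from cranial_iip.normative_model import fit_normative_regression

    _, cohort = noisy_cohort
    cohort = copy.deepcopy(cohort)  # this test removes a measurement
    fits = {
        r: fit_normative_regression(cohort, r, "density")
        for r in iip_risk.DEFAULT_FEATURE_REGIONS
    }
    ab = [r for r in cohort if r.group in ("normative", "IIP")]
    X, names = iip_risk.build_feature_matrix(ab, fits)
    y = np.array([1 if r.group == "IIP" else 0 for r in ab])
    model = fit_iip_classifier(X, y, feature_names=names, seed=0)
    broken = cohort[0]
    del broken.measurements[("global", "density")]
    scores = score_subjects(model, cohort, fits)
    assert np.isnan(scores.scores[0])
    finite = scores.scores[np.isfinite(scores.scores)]
    assert np.all((finite >= 0) & (finite <= 1))


# ---------------------------------------------------------------------------
# prevalence

def test_prevalence_matches_direct_count():
    s = _make_scores([0.1, 0.6, 0.7, 0.2, 0.9], ["a", "a", "a", "b", "b"])
    prev = estimate_prevalence(s, 0.5).set_index("group")
    assert prev.loc["a", "prevalence_pct"] == pytest.approx(100 * 2 / 3)
    assert prev.loc["b", "prevalence_pct"] == pytest.approx(50.0)


def test_prevalence_edge_thresholds():
    s = _make_scores([0.1, 0.2, 0.3], ["g", "g", "g"])
    assert estimate_prevalence(s, 0.0)["prevalence_pct"].iloc[0] == 100.0
    assert estimate_prevalence(s, 0.9)["prevalence_pct"].iloc[0] == 0.0


@settings(derandomize=True, max_examples=40)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.data())
def test_prevalence_monotone_in_threshold(vals, data):
    s = _make_scores(vals, ["g"] * len(vals))
    t1 = data.draw(st.floats(0, 1))
    t2 = data.draw(st.floats(0, 1))
    lo, hi = min(t1, t2), max(t1, t2)
    p_lo = estimate_prevalence(s, lo)["prevalence_pct"].iloc[0]
    p_hi = estimate_prevalence(s, hi)["prevalence_pct"].iloc[0]
    assert p_hi <= p_lo


def test_per_patient_prevalence_collapses_repeat_scans():
    s = RiskScores(
        scores=np.array([0.9, 0.05, 0.9, 0.9]),
        groups=np.array(["AS"] * 4),
        patient_ids=np.array(["p1", "p1", "p2", "p3"]),
    )
    per_scan = estimate_prevalence(s, 0.5).set_index("group")
    per_pat = estimate_prevalence(s, 0.5, per_patient=True).set_index("group")
    assert per_scan.loc["AS", "prevalence_pct"] == pytest.approx(75.0)
    assert per_pat.loc["AS", "n"] == 3
    assert per_pat.loc["AS", "prevalence_pct"] == pytest.approx(100 * 2 / 3)


# ---------------------------------------------------------------------------
# nonparametric comparisons

def _u_oracle(a, b):
    """Exhaustive pair counting for the Mann-Whitney U of sample a."""
    u = 0.0
    for x in a:
        for z in b:
            u += 1.0 if x > z else (0.5 if x == z else 0.0)
    return u


def test_mann_whitney_matches_exhaustive_enumeration():
    a = [3.1, 0.4, 2.2, 5.0]
    b = [1.0, 2.2, 0.1]
    s = _make_scores(a + b, ["x"] * 4 + ["y"] * 3)
    table = compare_risk_distributions(s, [("x", "y")])
    assert table["U"].iloc[0] == pytest.approx(_u_oracle(a, b))


def test_identical_distributions_fully_corrected():
    vals = [0.2, 0.5, 0.8, 0.4]
    s = _make_scores(vals + vals, ["x"] * 4 + ["y"] * 4)
    table = compare_risk_distributions(s, [("x", "y")])
    assert table["p_bonferroni"].iloc[0] == 1.0


def test_bonferroni_never_below_raw_p(noisy_cohort):
    rng = np.random.default_rng(8)
    s = _make_scores(rng.random(60), np.repeat(["a", "b", "c"], 20))
    table = compare_risk_distributions(s)
    assert (table["p_bonferroni"] >= table["p_raw"] - 1e-15).all()
    assert (table["p_bonferroni"] <= 1.0).all()
    assert (table["m"] == 3).all()


def test_undersized_group_comparison_rejected():
    s = _make_scores([0.1, 0.2, 0.3], ["a", "a", "b"])
    with pytest.raises(RiskModelError):
        compare_risk_distributions(s, [("a", "b")])


# ---------------------------------------------------------------------------
# risk-age correlation

def test_perfect_monotone_association_gives_rho_one():
    ages = np.array([0.1, 0.5, 1.0, 2.0, 3.0])
    rho, p = correlate_risk_age(ages**2, ages)
    assert rho == pytest.approx(1.0)


def _spearman_oracle(x, y):
    """Tie-corrected rank formula: Pearson correlation of average ranks."""

    def ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            r[order[i:j]] = (i + j - 1) / 2.0 + 1.0
            i = j
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def test_spearman_matches_rank_formula_with_ties():
    risk = [0.2, 0.8, 0.8, 0.1, 0.5, 0.3]
    age = [0.5, 2.0, 1.5, 0.2, 0.2, 1.0]
    rho, _ = correlate_risk_age(np.array(risk), np.array(age))
    assert rho == pytest.approx(_spearman_oracle(risk, age), abs=1e-12)


def test_spearman_is_symmetric():
    rng = np.random.default_rng(9)
    x, y = rng.random(15), rng.random(15)
    assert correlate_risk_age(x, y)[0] == pytest.approx(correlate_risk_age(y, x)[0])


def test_constant_input_yields_missing_with_warning():
    with pytest.warns(UserWarning, match="constant"):
        rho, p = correlate_risk_age(np.full(5, 0.5), np.arange(5.0))
    assert np.isnan(rho) and np.isnan(p)
    with pytest.raises(RiskModelError):
        correlate_risk_age(np.array([0.1, 0.2]), np.array([1.0, 2.0]))
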