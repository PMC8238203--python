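"""Accuracy, ROC/AUC, optimal operating point, prevalence sweep, baselines."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.optimize import minimize

import netsnp as ns


def test_accuracy_basic_and_tie_rule():
    assert ns.accuracy(np.array([0.4, -0.4]), np.array([1, 0])) == 100.0
    # CV of exactly zero predicts control
    cv = np.zeros(10)
    labels = np.r_[np.ones(3, int), np.zeros(7, int)]
    assert ns.accuracy(cv, labels) == pytest.approx(70.0)


def test_accuracy_outer_quantile_selection():
    cv = np.array([-0.4, -0.3, -0.2, -0.1, 0.1, 0.2, 0.3, 0.4])
    labels = (cv > 0).astype(int)
    # frac 0.25 on 8 values keeps exactly the 2 most extreme
    assert ns.accuracy(cv, labels, "outer_quantile", 0.25) == 100.0
    cv2 = cv.copy()
    cv2[0] = 0.45   # most-negative slot now mislabelled as extreme positive
    labels2 = labels.copy()
    assert ns.accuracy(cv2, labels2, "outer_quantile", 0.25) == 50.0


def test_accuracy_abs_cv_mode_and_frac_validation():
    cv = np.array([-0.5, -0.01, 0.01, 0.5])
    labels = np.array([0, 1, 0, 1])
    # top 50% by |CV| keeps the two extremes, both correct
    assert ns.accuracy(cv, labels, "abs_cv", 0.5) == 100.0
    with pytest.raises(ValueError):
        ns.accuracy(cv, labels, frac=0.0)


def test_accuracy_equals_confusion_matrix_identity():
    rng = np.random.default_rng(0)
    cv = rng.uniform(-0.5, 0.5, 200)
    labels = rng.integers(0, 2, 200)
    pred = (cv > 0).astype(int)
    fp = np.sum((pred == 1) & (labels == 0))
    fn = np.sum((pred == 0) & (labels == 1))
    assert ns.accuracy(cv, labels) == pytest.approx(100 * (1 - (fp + fn) / 200))


def test_roc_perfect_and_one_class_error():
    scores = np.array([0.9, 0.8, 0.2, 0.1])
    labels = np.array([1, 1, 0, 0])
    assert ns.roc_curve(scores, labels).auc == 1.0
    with pytest.raises(ValueError):
        ns.roc_curve(scores, np.ones(4, int))


def test_auc_equals_mann_whitney_u():
    rng = np.random.default_rng(1)
    for _ in range(20):
        n_p, n_n = rng.integers(5, 40, 2)
        scores = np.concatenate([rng.normal(0.6, 0.2, n_p), rng.normal(0.4, 0.2, n_n)])
        labels = np.r_[np.ones(n_p, int), np.zeros(n_n, int)]
        auc = ns.roc_curve(scores, labels).auc
        u = sps.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                             alternative="two-sided").statistic
        assert auc == pytest.approx(u / (n_p * n_n), abs=1e-10)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    scores = rng.uniform(0.01, 0.99, 100)
    labels = rng.integers(0, 2, 100)
    a1 = ns.roc_curve(scores, labels).auc
    a2 = ns.roc_curve(np.log(scores / (1 - scores)), labels).auc
    assert a1 == pytest.approx(a2, abs=1e-12)


@pytest.mark.parametrize("costs,np_nn,expect_s", [
    (dict(cost_p_given_n=1, cost_n_given_p=1), (10, 10), 1.0),
    (dict(cost_p_given_n=2, cost_n_given_p=1), (10, 20), 4.0),
])
def test_oop_slope_formula(costs, np_nn, expect_s):
    spec = ns.CostSpec(**costs)
    assert ns.oop_slope(spec, *np_nn) == pytest.approx(expect_s)


def _expected_cost(scores, labels, thr, costs, n_p, n_n):
    pred = scores >= thr
    tp = np.sum(pred & (labels == 1)) / max(np.sum(labels == 1), 1)
    fp = np.sum(pred & (labels == 0)) / max(np.sum(labels == 0), 1)
    return (n_p * (costs.cost_n_given_p * (1 - tp) + costs.cost_p_given_p * tp)
            + n_n * (costs.cost_p_given_n * fp + costs.cost_n_given_n * (1 - fp)))


def test_oop_matches_brute_force_cost_minimum():
    rng = np.random.default_rng(3)
    for _ in range(30):
        n_p, n_n = rng.integers(8, 40, 2)
        scores = np.concatenate([rng.beta(3, 2, n_p), rng.beta(2, 3, n_n)])
        labels = np.r_[np.ones(n_p, int), np.zeros(n_n, int)]
        costs = ns.CostSpec(cost_p_given_n=float(rng.uniform(0.5, 3)),
                            cost_n_given_p=float(rng.uniform(0.5, 3)))
        roc = ns.roc_curve(scores, labels)
        _, thr, _, _ = ns.optimal_operating_point(roc, costs, n_p, n_n)
        got = _expected_cost(scores, labels, thr, costs, n_p, n_n)
        grid = np.r_[np.unique(scores), np.inf]
        best = min(_expected_cost(scores, labels, t, costs, n_p, n_n) for t in grid)
        assert got == pytest.approx(best, abs=1e-9)


def test_prevalence_metrics_identities():
    rng = np.random.default_rng(4)
    cv = np.r_[rng.uniform(0, 0.5, 50), rng.uniform(-0.5, 0, 50)]
    labels = np.r_[np.ones(50, int), np.zeros(50, int)]
    grid = [0.05, 0.1, 0.3, 0.5]
    rows = ns.prevalence_metrics(cv, labels, grid)
    for row in rows:
        assert row["fdr"] + row["ppv"] == pytest.approx(1.0)
        assert row["fdr"] == 0.0     # perfect separation
    with pytest.raises(ValueError):
        ns.prevalence_metrics(cv, labels, [0.0, 0.5])


def test_uninformative_classifier_ppv_tracks_prevalence():
    rng = np.random.default_rng(5)
    cv = rng.uniform(-0.5, 0.5, 4000)
    labels = rng.integers(0, 2, 4000)
    rows = ns.prevalence_metrics(cv, labels, [0.2])
    # sens ~ spec-complement ~ 0.5 so PPV ~ prevalence, within sampling noise
    assert rows[0]["ppv"] == pytest.approx(0.2, abs=0.03)


def test_oop_cost_never_worse_than_fixed_threshold():
    rng = np.random.default_rng(6)
    for _ in range(10):
        cv = np.concatenate([rng.normal(0.1, 0.2, 60), rng.normal(-0.1, 0.2, 60)])
        cv = np.clip(cv, -0.5, 0.5)
        labels = np.r_[np.ones(60, int), np.zeros(60, int)]
        costs = ns.CostSpec()
        scores = cv + 0.5
        roc = ns.roc_curve(scores, labels)
        _, thr, _, _ = ns.optimal_operating_point(roc, costs, 60, 60)
        assert (_expected_cost(scores, labels, thr, costs, 60, 60)
                <= _expected_cost(scores, labels, 0.5, costs, 60, 60) + 1e-9)


# ----------------------------------------------------------------------


def test_logistic_baseline_separable_and_majority():
    rng = np.random.default_rng(7)
    x = np.vstack([rng.normal(size=(50, 2)) - 3, rng.normal(size=(50, 2)) + 3])
    y = np.r_[np.zeros(50, int), np.ones(50, int)]
    _, _, acc = ns.logistic_baseline(x, y, x, y)
    assert acc == 100.0
    xc = np.zeros((30, 2))
    yc = np.r_[np.ones(20, int), np.zeros(10, int)]
    _, pred, _ = ns.logistic_baseline(xc, yc, xc)
    assert np.all(pred == 1)    # constant features -> majority class


def test_logistic_coefficients_match_direct_likelihood_maximisation():
    rng = np.random.default_rng(8)
    x = rng.normal(size=(120, 3))
    logit = 0.5 + x @ np.array([1.0, -2.0, 0.5])
    y = (rng.random(120) < 1 / (1 + np.exp(-logit))).astype(int)
    beta, _, _ = ns.logistic_baseline(x, y, x, ridge=1e-6)

    xd = np.column_stack([np.ones(120), x])

    def nll(b):
        eta = xd @ b
        return float(np.sum(np.log1p(np.exp(-np.abs(eta))) + np.maximum(eta, 0) - y * eta)
                     + 1e-6 * np.sum(b[1:] ** 2))

    ref = minimize(nll, np.zeros(4), method="BFGS", options={"gtol": 1e-12}).x
    assert np.allclose(beta, ref, atol=1e-6)


def test_mcnemar_exact_binomial():
    labels = np.zeros(30, int)
    pred_a = labels.copy(); pred_b = labels.copy()
    pred_b[:10] = 1          # b = 10 (A right, B wrong)
    pred_a[10:30] = 1        # c = 20 (A wrong, B right)
    b, c, p = ns.mcnemar_test(pred_a, pred_b, labels)
    assert (b, c) == (10, 20)
    expect = float(sps.binomtest(10, 30, 0.5).pvalue)
    assert p == pytest.approx(expect, rel=1e-12)


def test_mcnemar_symmetry_and_no_discordance():
    labels = np.array([0, 1] * 10)
    pred_a = labels.copy(); pred_b = labels.copy()
    pred_a[0] ^= 1; pred_b[1] ^= 1    # b = c = 1
    _, _, p = ns.mcnemar_test(pred_a, pred_b, labels)
    assert p == pytest.approx(1.0)
    with pytest.warns(UserWarning):
        b, c, p = ns.mcnemar_test(labels, labels, labels)
    assert (b, c, p) == (0, 0, 1.0)
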