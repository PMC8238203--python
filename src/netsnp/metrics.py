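"""Classifier performance metrics.

Accuracy (full and confidence-restricted), ROC/AUC, the cost-based
optimal operating point, prevalence-swept FDR/PPV, a logistic-regression
baseline, and McNemar's paired comparison.

Sign conventions: the classifier value CV lies in [-0.5, +0.5]; at the
fixed threshold any strictly positive CV predicts case (CV = 0 predicts
control).  ROC analysis uses the [0,1]-normalised score P(case) = CV + 0.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

logger = logging.getLogger("netsnp")


def accuracy(cv: np.ndarray, labels: np.ndarray, mode: str = "all",
             frac: float = 1.0) -> float:
    """Percent correct at the fixed CV threshold of zero.

    ``mode="all"`` scores every individual; ``"outer_quantile"`` keeps the
    frac/2 lowest and frac/2 highest CVs (the most confident calls at both
    ends); ``"abs_cv"`` keeps the top ``frac`` by |CV|.
    """
    cv = np.asarray(cv, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if cv.shape != labels.shape:
        raise ValueError("cv and labels must align")
    if not (0 < frac <= 1):
        raise ValueError("frac must lie in (0, 1]")
    if mode == "all":
        keep = np.ones(cv.size, dtype=bool)
    elif mode == "outer_quantile":
        k = int(round(cv.size * frac / 2))
        order = np.argsort(cv, kind="stable")
        keep = np.zeros(cv.size, dtype=bool)
        keep[order[:k]] = True
        keep[order[cv.size - k:]] = True
    elif mode == "abs_cv":
        k = int(round(cv.size * frac))
        order = np.argsort(-np.abs(cv), kind="stable")
        keep = np.zeros(cv.size, dtype=bool)
        keep[order[:k]] = True
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pred = (cv[keep] > 0).astype(int)   # CV == 0 -> control
    return 100.0 * float(np.mean(pred == labels[keep]))


@dataclass
class RocData:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocData:
    """ROC from sweeping a threshold over [0,1] scores; trapezoid AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present for an ROC curve")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocData(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


@dataclass
class CostSpec:
    """Misclassification costs and the prevalence they apply at."""

    cost_p_given_n: float = 1.0   # misclassifying a control as case
    cost_n_given_n: float = 0.0
    cost_n_given_p: float = 1.0   # misclassifying a case as control
    cost_p_given_p: float = 0.0
    prevalence: float = 0.5

    def __post_init__(self):
        if not self.cost_n_given_p > self.cost_p_given_p:
            raise ValueError("cost(N|P) must exceed cost(P|P)")
        if not self.cost_p_given_n > self.cost_n_given_n:
            raise ValueError("cost(P|N) must exceed cost(N|N)")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")


def oop_slope(costs: CostSpec, n_pos: float, n_neg: float) -> float:
    """Cost slope S = (Cost(P|N)-Cost(N|N)) / (Cost(N|P)-Cost(P|P)) * N/P."""
    return ((costs.cost_p_given_n - costs.cost_n_given_n)
            / (costs.cost_n_given_p - costs.cost_p_given_p)
            * (n_neg / n_pos))


def optimal_operating_point(roc: RocData, costs: CostSpec,
                            n_pos: float, n_neg: float):
    """First ROC point touched by a line of slope S slid down-right from (0,1).

    Equivalently the point maximising TPR - S*FPR (ties resolved toward the
    smaller FPR, i.e. the first touch).  Returns (S, threshold, fpr, tpr).
    """
    if roc.fpr.size < 3:  # sklearn curves carry the two trivial endpoints
        raise ValueError("degenerate ROC curve (single operating point)")
    s = oop_slope(costs, n_pos, n_neg)
    intercept = roc.tpr - s * roc.fpr
    best = np.nonzero(intercept == intercept.max())[0]
    i = best[np.argmin(roc.fpr[best])]
    return s, float(roc.thresholds[i]), float(roc.fpr[i]), float(roc.tpr[i])


def prevalence_metrics(cv: np.ndarray, labels: np.ndarray,
                       prevalences: Sequence[float],
                       threshold_mode: str = "fixed_zero",
                       costs: Optional[CostSpec] = None,
                       resample: Optional[int] = None,
                       seed: int = 0):
    """FDR/PPV/sensitivity/specificity across a case-prevalence sweep.

    The empirical per-class error rates are computed once on the supplied
    individuals, then the confusion matrix is reweighted analytically to
    each target prevalence (a resampling mode with ``resample`` draws per
    point exists as a stochastic cross-check).  ``threshold_mode`` is
    ``fixed_zero`` (CV > 0 predicts case) or ``oop`` (per-prevalence
    cost-optimal threshold on the [0,1] score).
    """
    cv = np.asarray(cv, dtype=float)
    labels = np.asarray(labels, dtype=int)
    prevalences = np.asarray(prevalences, dtype=float)
    if ((prevalences <= 0) | (prevalences >= 1)).any():
        raise ValueError("prevalence grid must lie inside (0, 1)")
    scores = cv + 0.5
    rng = np.random.default_rng(seed)
    rows = []
    for prev in prevalences:
        if threshold_mode == "fixed_zero":
            thr = 0.5
        elif threshold_mode == "oop":
            c = costs or CostSpec(prevalence=prev)
            roc = roc_curve(scores, labels)
            _, thr, _, _ = optimal_operating_point(roc, c, n_pos=prev, n_neg=1 - prev)
        else:
            raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
        if resample:
            n_case = int(round(resample * prev))
            case_idx = rng.choice(np.nonzero(labels == 1)[0], n_case, replace=True)
            ctrl_idx = rng.choice(np.nonzero(labels == 0)[0], resample - n_case,
                                  replace=True)
            sub_s = np.concatenate([scores[case_idx], scores[ctrl_idx]])
            sub_l = np.concatenate([np.ones(n_case, int),
                                    np.zeros(resample - n_case, int)])
            sens = float(np.mean(sub_s[sub_l == 1] >= thr))
            spec = float(np.mean(sub_s[sub_l == 0] < thr))
        else:
            sens = float(np.mean(scores[labels == 1] >= thr))
            spec = float(np.mean(scores[labels == 0] < thr))
        tp = prev * sens
        fp = (1 - prev) * (1 - spec)
        fdr = fp / (fp + tp) if (fp + tp) > 0 else 0.0
        rows.append({"prevalence": float(prev), "threshold": float(thr),
                     "sensitivity": sens, "specificity": spec,
                     "fdr": fdr, "ppv": 1.0 - fdr})
    return rows


# ----------------------------------------------------------------------
# Baselines


def logistic_baseline(x_train: np.ndarray, y_train: np.ndarray,
                      x_test: np.ndarray, y_test: Optional[np.ndarray] = None,
                      ridge: float = 1e-6, max_iter: int = 100):
    """Maximum-likelihood logistic regression via IRLS (tiny ridge for
    separable data), thresholded at probability 0.5.

    Returns (coefficients incl. intercept, test predictions, accuracy %).
    """
    x = np.column_stack([np.ones(len(x_train)), x_train])
    y = np.asarray(y_train, dtype=float)
    beta = np.zeros(x.shape[1])
    pen = ridge * np.eye(x.shape[1])
    pen[0, 0] = 0.0   # intercept unpenalised
    for it in range(max_iter):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        wdiag = np.maximum(mu * (1 - mu), 1e-10)
        grad = x.T @ (y - mu) - 2 * pen @ beta
        hess = (x.T * wdiag) @ x + 2 * pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    else:
        raise RuntimeError(f"IRLS did not converge in {max_iter} iterations")
    xt = np.column_stack([np.ones(len(x_test)), x_test])
    proba = 1.0 / (1.0 + np.exp(-(xt @ beta)))
    pred = (proba >= 0.5).astype(int)
    acc = None
    if y_test is not None:
        acc = 100.0 * float(np.mean(pred == np.asarray(y_test, dtype=int)))
    return beta, pred, acc


def mcnemar_test(pred_a: np.ndarray, pred_b: np.ndarray, labels: np.ndarray,
                 exact: bool = True):
    """Paired comparison of two classifiers on the same individuals.

    ``b`` counts A-correct/B-wrong, ``c`` A-wrong/B-correct.  The exact
    two-sided p is binomial on (min(b,c), b+c) at 0.5; a continuity-
    corrected chi-square variant is available with ``exact=False``.
    """
    pred_a = np.asarray(pred_a, dtype=int)
    pred_b = np.asarray(pred_b, dtype=int)
    labels = np.asarray(labels, dtype=int)
    ok_a = pred_a == labels
    ok_b = pred_b == labels
    b = int(np.sum(ok_a & ~ok_b))
    c = int(np.sum(~ok_a & ok_b))
    if b + c == 0:
        warnings.warn("no discordant pairs; McNemar p-value is 1 by convention")
        return b, c, 1.0
    if exact:
        p = float(stats.binomtest(min(b, c), b + c, 0.5, alternative="two-sided").pvalue)
    else:
        chi2 = (abs(b - c) - 1) ** 2 / (b + c)
        p = float(stats.chi2.sf(chi2, df=1))
    return b, c, p
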