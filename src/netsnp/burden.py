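"""Per-individual tSNP burden and GLM slope validation.

The validation surface of the method: if netSNP-identified protective
and risk tSNPs are real, the number an individual harbors (minor-allele
dosage summed over the set, optionally weighted by |mCVt|) should
correlate with phenotypes never used in scoring -- age of disease
diagnosis (cases) and Braak neuropathology stage (autopsied
individuals).  Expected signs: protective burden correlates positively
with age of diagnosis and negatively with Braak stage; risk burden the
opposite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .store import GenotypeStore, SampleRecord, minor_allele_stats

logger = logging.getLogger("netsnp")


def minor_dosage(store: GenotypeStore, ids: Sequence[int],
                 loci: Sequence[int],
                 orientation_ids: Optional[Sequence[int]] = None) -> np.ndarray:
    """Minor-allele dosage matrix (0/1/2; missing = 0) for the given loci.

    Orientation follows the population minor allele (the whole store by
    default, or ``orientation_ids``): where the alternate allele is minor
    the dosage is the genotype code itself, where the reference allele is
    minor it is 2 - code.
    """
    ids = np.asarray(ids, dtype=int)
    loci = list(loci)
    stats = minor_allele_stats(store, orientation_ids)
    codes = store.dense_codes(ids, loci).astype(np.int64)
    missing = codes == -1
    dosage = np.empty_like(codes)
    for j, locus in enumerate(loci):
        if stats.mfa_is_alt[locus]:
            dosage[:, j] = codes[:, j]
        else:
            dosage[:, j] = 2 - codes[:, j]
    dosage[missing] = 0
    return dosage


def burden_counts(store: GenotypeStore, ids: Sequence[int],
                  loci_weights: dict, weighting: str = "none") -> np.ndarray:
    """Per-individual burden over one tSNP set.

    ``loci_weights`` maps locus index -> |mCVt|.  With ``weighting="none"``
    the burden is the summed minor-allele dosage; with ``"cvt"`` each
    dosage is scaled by the locus's |mCVt| weight.
    """
    loci = sorted(loci_weights)
    for locus in loci:
        if not (0 <= locus < store.n_loci):
            raise KeyError(f"locus {locus} absent from store")
    if not loci:
        return np.zeros(len(ids))
    dosage = minor_dosage(store, ids, loci)
    if weighting == "none":
        return dosage.sum(axis=1).astype(float)
    if weighting == "cvt":
        w = np.array([abs(loci_weights[l]) for l in loci], dtype=float)
        return dosage @ w
    raise ValueError(f"unknown weighting {weighting!r}")


@dataclass
class BurdenResult:
    """Raw and |mCVt|-weighted burden per individual, signs kept separate."""

    protective_count: np.ndarray
    risk_count: np.ndarray
    protective_weighted: np.ndarray
    risk_weighted: np.ndarray


def burden_result(store: GenotypeStore, ids: Sequence[int],
                  protective: dict, risk: dict) -> BurdenResult:
    overlap = set(protective) & set(risk)
    if overlap:
        raise ValueError(f"tSNP sets must be disjoint; shared loci {sorted(overlap)}")
    return BurdenResult(
        protective_count=burden_counts(store, ids, protective, "none"),
        risk_count=burden_counts(store, ids, risk, "none"),
        protective_weighted=burden_counts(store, ids, protective, "cvt"),
        risk_weighted=burden_counts(store, ids, risk, "cvt"),
    )


@dataclass
class GlmFit:
    """Single-predictor ordinary least squares fit with slope F-test."""

    beta: float
    intercept: float
    f_stat: float
    df_model: int
    df_resid: int
    p_value: float
    n: int


def glm_slope_test(x: np.ndarray, y: np.ndarray) -> GlmFit:
    """OLS of y on x with intercept; F-test of the slope on (1, n-2) df.

    The F statistic equals the squared t statistic of the slope; the
    p-value is the probability of a slope of such magnitude under the
    null hypothesis of no association.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must align")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope undefined")
    xm, ym = x - x.mean(), y - y.mean()
    sxx = float(xm @ xm)
    beta = float(xm @ ym) / sxx
    intercept = float(y.mean() - beta * x.mean())
    resid = ym - beta * xm
    sse = float(resid @ resid)
    ssr = beta * beta * sxx
    df_resid = n - 2
    if sse <= 0:
        return GlmFit(beta, intercept, np.inf, 1, df_resid, 0.0, n)
    f = ssr / (sse / df_resid)
    p = float(sps.f.sf(f, 1, df_resid))
    return GlmFit(beta, intercept, float(f), 1, df_resid, max(p, 0.0), n)


def validation_report(store: GenotypeStore, samples: Sequence[SampleRecord],
                      sample_rows: Sequence[int],
                      protective: dict, risk: dict,
                      cv: Optional[np.ndarray] = None,
                      published: Optional[dict] = None) -> pd.DataFrame:
    """GLM slope tests of each burden predictor against age and Braak.

    Rows: one regression per (predictor, response) pair.  Age regressions
    use case individuals; Braak regressions use autopsied individuals
    (cases and controls).  ``published`` optionally supplies an external
    SNP set (locus -> |mCVt| weight) mirroring the published-SNP
    comparison.  Expected signs are included for reference.
    """
    samples = list(samples)
    sample_rows = np.asarray(sample_rows, dtype=int)
    is_case = np.array([s.status == "case" for s in samples])
    has_braak = np.array([s.braak is not None for s in samples])
    ages = np.array([s.age for s in samples])
    braak = np.array([s.braak if s.braak is not None else np.nan for s in samples],
                     dtype=float)

    burdens = burden_result(store, sample_rows, protective, risk)
    predictors = {
        "protective_count": (burdens.protective_count, {"age": "+", "braak": "-"}),
        "risk_count": (burdens.risk_count, {"age": "-", "braak": "+"}),
        "protective_weighted": (burdens.protective_weighted, {"age": "+", "braak": "-"}),
        "risk_weighted": (burdens.risk_weighted, {"age": "-", "braak": "+"}),
    }
    if cv is not None:
        predictors["cv"] = (np.asarray(cv, dtype=float), {"age": "-", "braak": "+"})
    if published is not None:
        predictors["published_count"] = (
            burden_counts(store, sample_rows, published, "none"),
            {"age": "-", "braak": "+"})
        predictors["published_weighted"] = (
            burden_counts(store, sample_rows, published, "cvt"),
            {"age": "-", "braak": "+"})

    responses = {"age": (is_case, ages)}
    if has_braak.any():
        responses["braak"] = (has_braak, braak)
    else:
        logger.warning("no autopsied individuals: Braak rows omitted")

    rows = []
    for pname, (values, signs) in predictors.items():
        for rname, (mask, y) in responses.items():
            x = values[mask]
            if x.size < 3 or np.ptp(x) == 0:
                continue
            fit = glm_slope_test(x, y[mask])
            rows.append({"predictor": pname, "response": rname, "n": fit.n,
                         "beta": fit.beta, "F": fit.f_stat,
                         "df": (fit.df_model, fit.df_resid),
                         "p": fit.p_value, "expected_sign": signs[rname]})
    return pd.DataFrame(rows)
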