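"""Per-SNP Fisher's exact association, ranking, and Q-Q null calibration.

Each locus is summarised as a 2x2 table of (minor, reference) allele
counts in (cases, controls) -- allele-level counting, two chromosomes
per individual, missing genotypes excluded from both margins.  The
two-sided exact p-value (FishP) is the sum of hypergeometric
probabilities, over all tables with the observed margins, whose point
probability does not exceed that of the observed table.

Because exome spectra are dominated by rare alleles the hypergeometric
support is tiny for most loci, so FishP for an entire locus panel is
computed in a single vectorised enumeration rather than per-table calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .store import GenotypeStore, MinorAlleleStats, minor_allele_stats

logger = logging.getLogger("netsnp")

# relative slack for the "point probability <= observed" inclusion rule,
# so exact pmf ties survive floating-point evaluation
_TIE_SLACK = 1e-12


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_fishp(case_minor: int, case_ref: int,
                 ctrl_minor: int, ctrl_ref: int) -> float:
    """Two-sided Fisher's exact p for one 2x2 allele-count table."""
    table = np.array([[case_minor, case_ref, ctrl_minor, ctrl_ref]])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table.sum() == 0:
        raise ValueError("all-zero table has no defined p-value")
    return float(fisher_fishp_many(table[:, 0], table[:, 1],
                                   table[:, 2], table[:, 3])[0])


def fisher_fishp_many(case_minor, case_ref, ctrl_minor, ctrl_ref,
                      chunk_width: int = 256) -> np.ndarray:
    """Vectorised two-sided Fisher's exact p over many 2x2 tables.

    Enumerates the full hypergeometric support for every table; tables are
    processed in groups of comparable support width to bound the padded
    enumeration size.
    """
    a = np.asarray(case_minor, dtype=np.int64)
    b = np.asarray(case_ref, dtype=np.int64)
    c = np.asarray(ctrl_minor, dtype=np.int64)
    d = np.asarray(ctrl_ref, dtype=np.int64)
    m1 = a + b          # case alleles
    k = a + c           # total minor alleles
    n = a + b + c + d   # total alleles
    lo = np.maximum(0, k - (n - m1))
    hi = np.minimum(k, m1)
    width = hi - lo + 1

    p = np.ones(a.shape, dtype=np.float64)
    todo = np.nonzero(width > 1)[0]
    if todo.size == 0:
        return p
    order = todo[np.argsort(width[todo], kind="stable")]
    start = 0
    while start < order.size:
        w0 = int(width[order[start]])
        cap = max(w0 * 2, chunk_width)
        stop = start
        # group tables whose support widths are within 2x of the chunk head
        while stop < order.size and width[order[stop]] <= cap:
            stop += 1
        idx = order[start:stop]
        p[idx] = _fishp_block(a[idx], m1[idx], k[idx], n[idx],
                              lo[idx], int(width[idx].max()))
        start = stop
    return p


def _fishp_block(a, m1, k, n, lo, w_max) -> np.ndarray:
    """Enumerate support for a block of tables padded to width ``w_max``."""
    x = lo[:, None] + np.arange(w_max)[None, :]
    valid = x <= np.minimum(k, m1)[:, None]
    xx = np.where(valid, x, 0)
    logpmf = (_log_comb(m1[:, None], xx)
              + _log_comb((n - m1)[:, None], k[:, None] - xx)
              - _log_comb(n[:, None], k[:, None]))
    pmf = np.where(valid, np.exp(logpmf), 0.0)
    obs = np.take_along_axis(pmf, (a - lo)[:, None], axis=1)
    keep = pmf <= obs * (1.0 + _TIE_SLACK)
    return np.minimum((pmf * keep).sum(axis=1), 1.0)


# ----------------------------------------------------------------------


@dataclass
class SnpAssoc:
    """Association table for a locus panel over one sample subset."""

    locus_indices: np.ndarray
    case_minor: np.ndarray
    case_ref: np.ndarray
    ctrl_minor: np.ndarray
    ctrl_ref: np.ndarray
    fishp: np.ndarray
    maf: np.ndarray
    mfa_is_alt: np.ndarray

    def to_frame(self, store: GenotypeStore) -> pd.DataFrame:
        loci = [store.loci[i] for i in self.locus_indices]
        return pd.DataFrame({
            "chr": [l.chromosome for l in loci],
            "pos": [l.position for l in loci],
            "gene": [l.gene for l in loci],
            "maf": self.maf,
            "fishp": self.fishp,
            "mfa": np.where(self.mfa_is_alt, "alt", "ref"),
        })


def association_scan(store: GenotypeStore, ids: Sequence[int],
                     labels: np.ndarray) -> SnpAssoc:
    """FishP for every locus with defined MAF over the given sample rows.

    ``labels`` is a boolean case indicator aligned with ``ids``.  The
    minor-allele orientation (MFA) is determined on the full subset, then
    allele counts are split by case/control status.
    """
    ids = np.asarray(ids, dtype=int)
    labels = np.asarray(labels, dtype=bool)
    if ids.size != labels.size:
        raise ValueError("ids and labels must align")
    stats = minor_allele_stats(store, ids)
    case_rows = ids[labels]
    het_c, hom_c, mis_c = store.locus_code_counts(case_rows)
    alt_case = het_c + 2 * hom_c
    tot_case = 2 * (len(case_rows) - mis_c)
    alt_all = stats.alt_count
    tot_all = stats.total_alleles

    minor_case = np.where(stats.mfa_is_alt, alt_case, tot_case - alt_case)
    minor_all = stats.minor_count
    keep = np.nonzero(stats.defined)[0]
    n_drop = stats.defined.size - keep.size
    if n_drop:
        logger.info("dropping %d loci with undefined MAF in subset", n_drop)

    a = minor_case[keep]
    b = tot_case[keep] - a
    c = minor_all[keep] - a
    d = (tot_all[keep] - tot_case[keep]) - c
    fishp = fisher_fishp_many(a, b, c, d)
    return SnpAssoc(locus_indices=keep, case_minor=a, case_ref=b,
                    ctrl_minor=c, ctrl_ref=d, fishp=fishp,
                    maf=stats.maf[keep], mfa_is_alt=stats.mfa_is_alt[keep])


def rank_snps(store: GenotypeStore, ids: Sequence[int], labels: np.ndarray,
              exclude_genes: Sequence[str] = (),
              exclude_loci: Sequence[tuple] = (),
              top_k: int = 50,
              rank_window: Optional[tuple[int, int]] = None,
              assoc: Optional[SnpAssoc] = None) -> tuple[np.ndarray, SnpAssoc]:
    """Rank loci ascending by FishP (ties by chromosome, position).

    Loci annotated to an excluded gene or matching an excluded
    (chrom, pos, alt) key are removed before selection.  Returns either
    the ``top_k`` first loci or, if ``rank_window=(lo, hi)`` is given,
    the loci ranked lo..hi (1-based, inclusive).
    """
    labels = np.asarray(labels, dtype=bool)
    n_case, n_ctrl = int(labels.sum()), int((~labels).sum())
    if n_case != n_ctrl:
        logger.warning("ranking on an unbalanced subset: %d cases vs %d controls",
                       n_case, n_ctrl)
    if assoc is None:
        assoc = association_scan(store, ids, labels)
    genes = np.array([store.loci[i].gene or "" for i in assoc.locus_indices])
    keys = [store.loci[i].key for i in assoc.locus_indices]
    mask = ~np.isin(genes, list(exclude_genes))
    if exclude_loci:
        excl = set(exclude_loci)
        mask &= np.array([kk not in excl for kk in keys])
    chrom = np.array([store.loci[i].chromosome for i in assoc.locus_indices])
    pos = np.array([store.loci[i].position for i in assoc.locus_indices])
    cand = np.nonzero(mask)[0]
    order = cand[np.lexsort((pos[cand], chrom[cand], assoc.fishp[cand]))]
    if rank_window is not None:
        lo, hi = rank_window
        if hi > order.size:
            raise ValueError(f"rank window {rank_window} exceeds {order.size} loci")
        sel = order[lo - 1:hi]
    else:
        if top_k > order.size:
            raise ValueError(f"top_k={top_k} exceeds {order.size} available loci")
        sel = order[:top_k]
    return assoc.locus_indices[sel], assoc


# ----------------------------------------------------------------------


@dataclass
class QQData:
    """Observed and label-shuffled -log10(FishP) quantiles.

    ``null_quantiles`` holds one sorted vector per shuffle; the chance
    band at each quantile rank is the min/max across shuffles, mirroring
    the shuffle-vs-shuffle scatter used to delimit chance behaviour.
    """

    observed: np.ndarray
    null_quantiles: np.ndarray  # (n_shuffles, n_loci)
    seed: int

    @property
    def band_low(self) -> np.ndarray:
        return self.null_quantiles.min(axis=0)

    @property
    def band_high(self) -> np.ndarray:
        return self.null_quantiles.max(axis=0)

    def fraction_inside_band(self) -> float:
        inside = (self.observed >= self.band_low) & (self.observed <= self.band_high)
        return float(inside.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"observed": self.observed,
                             "band_low": self.band_low,
                             "band_high": self.band_high})


def qq_null_band(store: GenotypeStore, ids: Sequence[int], labels: np.ndarray,
                 n_shuffles: int = 100, seed: int = 0,
                 exclude_chromosome: Optional[str] = None) -> QQData:
    """Q-Q calibration of observed FishP against label-shuffled nulls.

    Every shuffle permutes case/control labels over the same individuals
    (case and control totals preserved) and recomputes FishP for the full
    locus panel; quantiles are sorted -log10 values over loci with defined
    MAF (optionally with one chromosome's loci removed first).
    """
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles to form a band")
    ids = np.asarray(ids, dtype=int)
    labels = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)

    def quantiles(lab):
        assoc = association_scan(store, ids, lab)
        keep = np.ones(assoc.locus_indices.size, dtype=bool)
        if exclude_chromosome is not None:
            chrom = np.array([store.loci[i].chromosome
                              for i in assoc.locus_indices])
            keep = chrom != exclude_chromosome
        return np.sort(-np.log10(assoc.fishp[keep]))

    observed = quantiles(labels)
    nulls = np.empty((n_shuffles, observed.size))
    for s in range(n_shuffles):
        nulls[s] = quantiles(rng.permutation(labels))
    return QQData(observed=observed, null_quantiles=nulls, seed=seed)
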