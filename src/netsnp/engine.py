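"""netSNP: permutation-importance scoring of individual variants.

A trained case/control network is probed by *assigning* every holdout
individual a fixed genotype at one target SNP (tSNP) and measuring how
the classifier value (CV) distribution shifts.  For each of ``n_reps``
repetitions a fresh ~70% training subset of a balanced sample set is
drawn, SNPs are re-ranked by Fisher's exact p-value on that subset, a
network is trained on the target SNP plus the 49 best-ranked other SNPs,
and four holdout score sets are recorded:

    NAT -- true genotypes;
    REF -- target forced homozygous for the non-minor allele;
    ALT -- target forced homozygous for the minor frequency allele (MFA);
    DIF -- ALT - REF, elementwise.

The mean ALT score over all individuals and repetitions (mCVt) is the
tSNP's importance weight: negative mCVt marks a protective minor allele,
positive mCVt a risk allele.  Significance is calibrated empirically
against mCVt values of randomly chosen target SNPs.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .assoc import association_scan, rank_snps
from .network import FeatureScaling, NetConfig, TrainedNet, build_feature_matrix, train_patternnet
from .store import GenotypeStore, minor_allele_stats

logger = logging.getLogger("netsnp")


def derive_seed(master_seed: int, *parts) -> int:
    """Stable child seed below 2^31 from a master seed and context labels."""
    text = ":".join(str(p) for p in (master_seed, *parts))
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def assign_genotype(features: np.ndarray, column: int, code: int,
                    scaling: FeatureScaling) -> np.ndarray:
    """Copy of a scaled feature matrix with one column forced to ``code``.

    The genotype code in {0,1,2} is pushed through the same per-feature
    affine map used at training time; all other columns are untouched and
    the input matrix is never modified.
    """
    if not (0 <= column < features.shape[1]):
        raise IndexError(f"column {column} out of range")
    if code not in (0, 1, 2):
        raise ValueError("assigned code must be in {0, 1, 2}")
    out = features.copy()
    lo, hi = scaling.lo[column], scaling.hi[column]
    span = hi - lo
    val = 2.0 * (code - lo) / span - 1.0 if span > 0 else 0.0
    out[:, column] = np.clip(val, -1.0, 1.0)
    return out


@dataclass
class TSnpResult:
    """Scores for one target SNP across repetitions."""

    locus_index: int
    nat: list          # per-repetition holdout CV arrays (true genotypes)
    ref: list          # target forced homozygous non-minor
    alt: list          # target forced homozygous MFA
    dif: list          # alt - ref
    mcvt: float        # mean ALT over all individuals x repetitions
    dispersion: float  # standard error of the per-repetition mean ALT
    n_reps: int
    mfa_is_alt: bool

    @property
    def mean_nat(self) -> float:
        return float(np.mean(np.concatenate(self.nat)))

    @property
    def mean_dif(self) -> float:
        return float(np.mean(np.concatenate(self.dif)))


def _balanced_subsample(rng, case_rows, ctrl_rows, frac):
    n_case = int(round(len(case_rows) * frac))
    n_ctrl = int(round(len(ctrl_rows) * frac))
    tr_case = rng.choice(case_rows, size=n_case, replace=False)
    tr_ctrl = rng.choice(ctrl_rows, size=n_ctrl, replace=False)
    return tr_case, tr_ctrl


def _split_validation(rng, rows, frac):
    rows = np.asarray(rows)
    n_val = int(round(len(rows) * frac))
    pick = rng.permutation(len(rows))
    return rows[pick[n_val:]], rows[pick[:n_val]]


def evaluate_tsnp(store: GenotypeStore,
                  ids: Sequence[int], labels: np.ndarray,
                  target_locus: int,
                  n_reps: int = 20,
                  config: Optional[NetConfig] = None,
                  top_k: int = 50,
                  train_frac: float = 0.7,
                  validation_frac: float = 0.15,
                  exclude_genes: Sequence[str] = (),
                  seed: int = 0,
                  fixed_holdout: bool = False) -> TSnpResult:
    """Score one target SNP by repeated train/assign/evaluate cycles.

    ``ids``/``labels`` describe a case:control balanced sample set (row
    indices into the store and a boolean case indicator).  Each repetition
    draws a fresh ~``train_frac`` training subset, ranks SNPs by training
    FishP, trains on the target plus the ``top_k - 1`` best other SNPs and
    scores the remaining individuals as holdout (with ``fixed_holdout``
    the first repetition's holdout is reused).  Deterministic given
    ``seed``; repetition r uses a child seed derived from
    (seed, target locus, r) so tSNP evaluations are independent.
    """
    if not (0 <= target_locus < store.n_loci):
        raise IndexError(f"target locus {target_locus} not in store")
    config = config or NetConfig()
    ids = np.asarray(ids, dtype=int)
    labels = np.asarray(labels, dtype=bool)
    case_rows, ctrl_rows = ids[labels], ids[~labels]

    # MFA orientation of the target, fixed over the balanced set: ALT forces
    # homozygosity for the minor allele; REF the opposite homozygote.
    tstats = minor_allele_stats(store, ids)
    if not tstats.defined[target_locus]:
        raise ValueError("target locus has no defined MAF in the sample set")
    mfa_is_alt = bool(tstats.mfa_is_alt[target_locus])
    alt_code, ref_code = (2, 0) if mfa_is_alt else (0, 2)

    fixed_hold_rows = None
    nat, ref, alt, dif = [], [], [], []
    rep_means = []
    for rep in range(n_reps):
        rng = np.random.default_rng(derive_seed(seed, "tsnp", target_locus, rep))
        tr_case, tr_ctrl = _balanced_subsample(rng, case_rows, ctrl_rows, train_frac)
        hold = np.setdiff1d(ids, np.concatenate([tr_case, tr_ctrl]))
        if fixed_holdout:
            if fixed_hold_rows is None:
                fixed_hold_rows = hold
            else:
                hold = fixed_hold_rows
                tr_case = np.setdiff1d(case_rows, hold)
                tr_ctrl = np.setdiff1d(ctrl_rows, hold)
                k_case = int(round(len(case_rows) * train_frac))
                k_ctrl = int(round(len(ctrl_rows) * train_frac))
                tr_case = rng.choice(tr_case, size=min(k_case, len(tr_case)), replace=False)
                tr_ctrl = rng.choice(tr_ctrl, size=min(k_ctrl, len(tr_ctrl)), replace=False)
        tr_case, val_case = _split_validation(rng, tr_case, validation_frac)
        tr_ctrl, val_ctrl = _split_validation(rng, tr_ctrl, validation_frac)
        train_rows = np.concatenate([tr_case, tr_ctrl])
        val_rows = np.concatenate([val_case, val_ctrl])
        y_train = np.concatenate([np.ones(len(tr_case), int), np.zeros(len(tr_ctrl), int)])
        y_val = np.concatenate([np.ones(len(val_case), int), np.zeros(len(val_ctrl), int)])
        y_train_b = y_train.astype(bool)

        ranked, _ = rank_snps(store, train_rows, y_train_b,
                              exclude_genes=exclude_genes,
                              exclude_loci=[store.loci[target_locus].key],
                              top_k=top_k - 1)
        feature_loci = [target_locus] + list(ranked)

        x_train, scaling = build_feature_matrix(store, train_rows, feature_loci)
        x_val = scaling.apply(store.feature_codes(val_rows, feature_loci))
        rep_cfg = NetConfig(hidden_layers=config.hidden_layers,
                            max_epochs=config.max_epochs,
                            min_grad=config.min_grad,
                            max_fails=config.max_fails,
                            wt_sigma=config.wt_sigma,
                            lambda0=config.lambda0,
                            reg=config.reg,
                            seed=derive_seed(seed, "net", target_locus, rep))
        net = train_patternnet(x_train, y_train, x_val, y_val, rep_cfg,
                               feature_loci=feature_loci, scaling=scaling)

        x_hold = scaling.apply(store.feature_codes(hold, feature_loci))
        cv_nat = net.predict_cv(x_hold)
        cv_ref = net.predict_cv(assign_genotype(x_hold, 0, ref_code, scaling))
        cv_alt = net.predict_cv(assign_genotype(x_hold, 0, alt_code, scaling))
        nat.append(cv_nat)
        ref.append(cv_ref)
        alt.append(cv_alt)
        dif.append(cv_alt - cv_ref)
        rep_means.append(float(cv_alt.mean()))

    pooled_alt = np.concatenate(alt)
    mcvt = float(pooled_alt.mean())
    disp = float(np.std(rep_means, ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
    return TSnpResult(locus_index=target_locus, nat=nat, ref=ref, alt=alt,
                      dif=dif, mcvt=mcvt, dispersion=disp, n_reps=n_reps,
                      mfa_is_alt=mfa_is_alt)


# ----------------------------------------------------------------------
# APOE-style two-locus genotype assignment

# genotype -> (epsilon-2 allele count, epsilon-4 allele count)
APOE_CODE_PAIRS = {
    "e22": (2, 0), "e23": (1, 0), "e24": (1, 1),
    "e33": (0, 0), "e34": (0, 1), "e44": (0, 2),
}


def apoe_genotype_assignment(net: TrainedNet, features: np.ndarray,
                             e2_column: int, e4_column: int,
                             genotype: str) -> np.ndarray:
    """CVs after assigning every individual a full two-locus APOE genotype.

    The two pseudo-loci code the epsilon-2 and epsilon-4 allele counts;
    e.g. e22 -> (2, 0), e34 -> (0, 1).  Both columns are forced to the
    scaled representation of the requested counts; all other genotypes
    stay untouched.
    """
    if genotype not in APOE_CODE_PAIRS:
        raise ValueError(f"unknown APOE genotype {genotype!r}")
    ncols = features.shape[1]
    if not (0 <= e2_column < ncols and 0 <= e4_column < ncols):
        raise ValueError("APOE columns are not among the network features")
    c2, c4 = APOE_CODE_PAIRS[genotype]
    x = assign_genotype(features, e2_column, c2, net.scaling)
    x = assign_genotype(x, e4_column, c4, net.scaling)
    return net.predict_cv(x)


# ----------------------------------------------------------------------
# Null calibration and classification


@dataclass
class NullBand:
    """Empirical mCVt distribution of randomly chosen target SNPs."""

    mcvts: np.ndarray
    alpha: float
    n_random: int
    seed: int
    n_reps_per_target: int

    @property
    def lower(self) -> float:
        return float(np.quantile(self.mcvts, self.alpha / 2))

    @property
    def upper(self) -> float:
        return float(np.quantile(self.mcvts, 1 - self.alpha / 2))


def null_band_mcvt(store: GenotypeStore, ids: Sequence[int], labels: np.ndarray,
                   n_random: int = 1000, alpha: float = 0.05,
                   config: Optional[NetConfig] = None,
                   n_reps: int = 5, top_k: int = 50,
                   train_frac: float = 0.7,
                   exclude_genes: Sequence[str] = (),
                   seed: int = 0) -> NullBand:
    """mCVt band from target SNPs drawn uniformly from all store loci.

    Random targets use a reduced repetition count (default 5 instead of
    the 20 used for real tSNPs) for tractability; that choice is recorded
    in the returned metadata.
    """
    if n_random < 100:
        raise ValueError("n_random must be at least 100 for a stable band")
    if n_random > store.n_loci:
        raise ValueError("n_random exceeds the number of store loci")
    rng = np.random.default_rng(derive_seed(seed, "null-band"))
    targets = rng.choice(store.n_loci, size=n_random, replace=False)
    stats = minor_allele_stats(store, np.asarray(ids, dtype=int))
    mcvts = []
    for t in targets:
        if not stats.defined[t]:
            continue
        res = evaluate_tsnp(store, ids, labels, int(t), n_reps=n_reps,
                            config=config, top_k=top_k, train_frac=train_frac,
                            exclude_genes=exclude_genes, seed=seed)
        mcvts.append(res.mcvt)
    return NullBand(mcvts=np.array(mcvts), alpha=alpha, n_random=n_random,
                    seed=seed, n_reps_per_target=n_reps)


def classify_tsnps(results: Sequence[TSnpResult], band: NullBand):
    """Partition tSNPs into protective / risk / indeterminate sets.

    A tSNP is protective when its mCVt falls below the band's lower
    quantile, risk when above the upper quantile.  The empirical
    two-sided p per tSNP is twice the smaller rank-based tail proportion
    of its mCVt within the null sample.
    """
    if not results:
        raise ValueError("no tSNP results to classify")
    null = np.sort(band.mcvts)
    n = null.size
    protective, risk, indeterminate = [], [], []
    p_emp = {}
    for res in results:
        lo_tail = np.searchsorted(null, res.mcvt, side="right") / n
        hi_tail = (n - np.searchsorted(null, res.mcvt, side="left")) / n
        p_emp[res.locus_index] = min(1.0, 2.0 * min(lo_tail, hi_tail))
        if res.mcvt < band.lower:
            protective.append(res.locus_index)
        elif res.mcvt > band.upper:
            risk.append(res.locus_index)
        else:
            indeterminate.append(res.locus_index)
    return {"protective": protective, "risk": risk,
            "indeterminate": indeterminate, "p_empirical": p_emp}
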