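"""Synthetic exome-like cohort generation with known ground truth.

Emulates the structure of a large case/control sequencing consortium:
~24 cohorts of varying case:control imbalance, a rare-skewed allele
frequency spectrum (>=95% of loci with MAF < 0.01), two planted common
loci mimicking APOE epsilon-4 (MAF 0.147, risk) and epsilon-2 (MAF
0.076, protective), optional graded rare planted effects, and age /
Braak phenotypes driven by the planted genetic burden.  The generator is
deliberately simple population genetics -- per-locus binomial draws with
optional copy-based LD blocks -- because the downstream method consumes
genotype codes, not haplotypes.

Disease status follows the same genotype-conditional odds mechanism as
the constructed-disease simulator: an individual carrying planted
alleles has control/case odds

    odds = baseline * prod_i (o_i / baseline) ** carrier_i

with baseline 0.89, which reduces exactly to the per-group odds for
single-locus carriers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.stats import spearmanr

from .store import GenotypeStore, LocusMeta, SampleRecord

logger = logging.getLogger("netsnp")

BASELINE_ODDS = 0.89   # control/case odds for carriers of no planted allele


@dataclass(frozen=True)
class PlantedEffect:
    """One planted disease locus: carrier control/case odds and its role."""

    locus: int
    maf: float
    control_case_odds: float
    tag: str                 # "risk" | "protective"
    gene: Optional[str] = None
    model: str = "carrier"   # "carrier": dominant (>=1 minor allele);
    #                          "dosage": per-allele multiplicative, the
    #                          dose-dependence real APOE shows

    def __post_init__(self):
        if not self.control_case_odds > 0:
            raise ValueError("odds must be positive")
        if self.tag not in ("risk", "protective"):
            raise ValueError("tag must be risk|protective")
        if self.model not in ("carrier", "dosage"):
            raise ValueError("model must be carrier|dosage")


@dataclass
class LdBlock:
    anchor: int
    companions: tuple[int, ...]
    correlation: float


@dataclass
class SynthSpec:
    """Full parameterisation of the synthetic cohort generator."""

    n_samples: int = 6000
    n_snps: int = 10_000
    # rare-skewed MAF spectrum: mixture of a rare band (96% weight) and a
    # uniform common tail
    rare_weight: float = 0.96
    rare_band: tuple[float, float] = (0.001, 0.008)
    common_band: tuple[float, float] = (0.02, 0.35)
    n_cohorts: int = 24
    planted_effects: tuple[PlantedEffect, ...] = ()
    ld_blocks: tuple[LdBlock, ...] = ()
    missing_rate: float = 0.002
    # age model: baseline mean (years), per-risk-allele shift,
    # per-protective-allele shift, noise sd; control ages are drawn around
    # the (older) age at last visit and carry no genetic signal
    age_baseline_case: float = 75.4
    age_risk_shift: float = -8.4
    age_protective_shift: float = 3.8
    age_sd: float = 8.0
    age_baseline_control: float = 86.1
    # Braak model: latent weight on signed burden and increasing stage cuts
    braak_weight: float = 0.8
    braak_thresholds: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0)
    autopsy_frac: float = 0.28
    seed: int = 0

    def __post_init__(self):
        if len(set(p.locus for p in self.planted_effects)) != len(self.planted_effects):
            raise ValueError("planted loci must be distinct")
        if any(p.locus >= self.n_snps for p in self.planted_effects):
            raise ValueError("planted locus index exceeds n_snps")
        if list(self.braak_thresholds) != sorted(self.braak_thresholds):
            raise ValueError("braak thresholds must be increasing")


def default_planted_effects() -> tuple[PlantedEffect, ...]:
    """The two common APOE-like loci the default cohort always carries."""
    return (
        PlantedEffect(locus=0, maf=0.147, control_case_odds=0.30,
                      tag="risk", gene="E4LIKE"),
        PlantedEffect(locus=1, maf=0.076, control_case_odds=2.41,
                      tag="protective", gene="E2LIKE"),
    )


def graded_planted_effects(start_locus: int = 2,
                           maf: float = 0.05) -> tuple[PlantedEffect, ...]:
    """Eight planted loci with graded carrier odds, four protective and
    four risk, used for sign- and rank-recovery evaluations."""
    prot = [3.0, 2.41, 2.0, 1.5]
    risk = [0.33, 0.41, 0.5, 0.67]
    effects = []
    for i, o in enumerate(prot + risk):
        tag = "protective" if o > 1 else "risk"
        effects.append(PlantedEffect(locus=start_locus + i, maf=maf,
                                     control_case_odds=o, tag=tag,
                                     gene=f"PLANT{i + 1}"))
    return tuple(effects)


def default_spec(seed: int = 0, **overrides) -> SynthSpec:
    planted = overrides.pop("planted_effects",
                            default_planted_effects() + graded_planted_effects())
    return SynthSpec(planted_effects=planted, seed=seed, **overrides)


# ----------------------------------------------------------------------


def _cohort_profile(n_cohorts: int):
    """Half balanced cohorts, a quarter case-heavy, a quarter control-heavy."""
    shares = []
    for i in range(n_cohorts):
        if i < n_cohorts // 2:
            shares.append(0.5)
        elif i < 3 * n_cohorts // 4:
            shares.append(0.8)
        else:
            shares.append(0.2)
    return np.array(shares)


def generate_cohort(spec: SynthSpec):
    """Generate (GenotypeStore, SampleRecord table, ground-truth manifest)."""
    if len(spec.planted_effects) > spec.n_snps:
        raise ValueError("more planted loci than loci")
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_snps

    # -- allele frequencies
    maf = np.where(rng.random(m) < spec.rare_weight,
                   rng.uniform(*spec.rare_band, size=m),
                   rng.uniform(*spec.common_band, size=m))
    for eff in spec.planted_effects:
        maf[eff.locus] = eff.maf

    # -- genotypes (alt allele is the minor allele by construction)
    codes = rng.binomial(2, maf[None, :], size=(n, m)).astype(np.int8)
    for block in spec.ld_blocks:
        for comp in block.companions:
            copy = rng.random(n) < block.correlation
            fresh = rng.binomial(2, maf[block.anchor], size=n).astype(np.int8)
            codes[:, comp] = np.where(copy, codes[:, block.anchor], fresh)

    # -- disease status from planted carrier odds (multiplicative in log odds)
    log_odds = np.full(n, np.log(BASELINE_ODDS))
    for eff in spec.planted_effects:
        shift = np.log(eff.control_case_odds) - np.log(BASELINE_ODDS)
        if eff.model == "carrier":
            log_odds += (codes[:, eff.locus] >= 1) * shift
        else:   # per-allele dose effect
            log_odds += codes[:, eff.locus] * shift
    p_control = 1.0 / (1.0 + np.exp(-log_odds))
    is_case = rng.random(n) >= p_control

    # -- missingness, applied after status so truth is exact
    if spec.missing_rate > 0:
        miss = rng.random((n, m)) < spec.missing_rate
        codes = np.where(miss, np.int8(-1), codes)

    # -- cohorts with configured imbalance, assigned conditionally on status
    shares = _cohort_profile(spec.n_cohorts)
    w_case = shares / shares.sum()
    w_ctrl = (1 - shares) / (1 - shares).sum()
    cohort_idx = np.empty(n, dtype=int)
    cohort_idx[is_case] = rng.choice(spec.n_cohorts, size=int(is_case.sum()), p=w_case)
    cohort_idx[~is_case] = rng.choice(spec.n_cohorts, size=int((~is_case).sum()), p=w_ctrl)
    cohort_names = [f"C{i + 1:02d}" for i in range(spec.n_cohorts)]

    # -- burden-driven phenotypes
    risk_dose = np.zeros(n)
    prot_dose = np.zeros(n)
    for eff in spec.planted_effects:
        dose = np.maximum(codes[:, eff.locus], 0)
        if eff.tag == "risk":
            risk_dose += dose
        else:
            prot_dose += dose
    age_case = (spec.age_baseline_case
                + spec.age_risk_shift * risk_dose
                + spec.age_protective_shift * prot_dose
                + rng.normal(0, spec.age_sd, n))
    age_ctrl = spec.age_baseline_control + rng.normal(0, spec.age_sd / 2, n)
    age = np.clip(np.where(is_case, age_case, age_ctrl), 40.0, 110.0)

    latent = spec.braak_weight * (risk_dose - prot_dose) + rng.normal(0, 1, n)
    stage = 1 + np.searchsorted(np.asarray(spec.braak_thresholds), latent)
    stage = np.clip(stage, 1, 6)
    autopsied = rng.random(n) < spec.autopsy_frac

    # -- containers
    loci = [LocusMeta(chromosome=str(1 + (j % 22)), position=10_000 + 100 * j,
                      ref_allele="A", alt_allele="G",
                      gene=next((e.gene for e in spec.planted_effects
                                 if e.locus == j and e.gene), f"G{j:05d}"))
            for j in range(m)]
    sample_ids = [f"S{i + 1:06d}" for i in range(n)]
    store = GenotypeStore(sample_ids, loci, sparse.csc_matrix(codes))
    records = [SampleRecord(sample_id=sample_ids[i],
                            cohort=cohort_names[cohort_idx[i]],
                            status="case" if is_case[i] else "control",
                            age=float(age[i]),
                            braak=int(stage[i]) if autopsied[i] else None)
               for i in range(n)]
    manifest = {
        "seed": spec.seed,
        "n_samples": n,
        "n_snps": m,
        "baseline_odds": BASELINE_ODDS,
        "planted": [{
            "locus": e.locus, "maf": e.maf, "odds": e.control_case_odds,
            "tag": e.tag, "gene": e.gene, "model": e.model,
            "log_odds_effect": float(np.log(e.control_case_odds)
                                     - np.log(BASELINE_ODDS)),
        } for e in spec.planted_effects],
        "true_maf": maf,
    }
    return store, records, manifest


def write_vcf(store: GenotypeStore, path) -> None:
    """Plain-text VCF v4.2 export (GT only) so the real entry point can be
    exercised end to end."""
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene label">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({l.chromosome for l in store.loci})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(store.sample_ids) + "\n")
        codes = store.dense_codes()
        for j, locus in enumerate(store.loci):
            info = f"GENE={locus.gene}" if locus.gene else "."
            gts = "\t".join(code_to_gt[int(c)] for c in codes[:, j])
            fh.write(f"{locus.chromosome}\t{locus.position}\t.\t{locus.ref_allele}"
                     f"\t{locus.alt_allele}\t.\tPASS\t{info}\tGT\t{gts}\n")


# ----------------------------------------------------------------------


@dataclass
class TruthEval:
    sign_recovery: float
    rank_correlation: float
    false_positive_rate: Optional[float]
    n_planted_tested: int


def truth_eval(manifest: dict, results: Sequence, classification: Optional[dict] = None) -> TruthEval:
    """Score tSNP results against the generator's ground truth.

    Sign recovery is the fraction of planted loci whose mCVt sign matches
    their tag (risk -> positive, protective -> negative); rank correlation
    is the Spearman correlation between |log-odds effect| and |mCVt| over
    the tested planted loci.  When a classification (from a null band) is
    supplied, the false positive rate among tested non-planted loci is
    also reported.
    """
    planted = {p["locus"]: p for p in manifest["planted"]}
    by_locus = {r.locus_index: r for r in results}
    tested_planted = [l for l in by_locus if l in planted]
    if not tested_planted:
        raise ValueError("no overlap between tested and planted loci")
    signs_ok = 0
    effects, mags = [], []
    for l in tested_planted:
        want = 1.0 if planted[l]["tag"] == "risk" else -1.0
        signs_ok += int(np.sign(by_locus[l].mcvt) == want)
        effects.append(abs(planted[l]["log_odds_effect"]))
        mags.append(abs(by_locus[l].mcvt))
    rank_corr = float(spearmanr(effects, mags).statistic) if len(effects) > 2 else np.nan
    fpr = None
    if classification is not None:
        non_planted = [l for l in by_locus if l not in planted]
        if non_planted:
            sig = set(classification["protective"]) | set(classification["risk"])
            fpr = float(np.mean([l in sig for l in non_planted]))
    return TruthEval(sign_recovery=signs_ok / len(tested_planted),
                     rank_correlation=rank_corr,
                     false_positive_rate=fpr,
                     n_planted_tested=len(tested_planted))
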