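"""Constructed ("bad") disease simulation over an existing population.

A constructed disease (BD) assigns case/control status from real
genotypes at two chosen loci via fixed control/case odds -- the same
odds APOE confers for Alzheimer's disease: carriers of the e4-like
allele are assigned control with odds 0.30, carriers of the e2-like
allele with odds 2.41, and everyone else with odds 0.89 (the e33
baseline).  Because a BD is, by construction, linked only to its two
defining loci, running the full discovery pipeline on a BD population is
a negative control: any burden-vs-age correlation found off the BD
chromosome would indicate method bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .network import NetConfig
from .store import GenotypeStore, SampleRecord, minor_allele_stats

logger = logging.getLogger("netsnp")

# default control/case odds per genotype group (APOE-derived)
DEFAULT_BD_ODDS = {"e4": 0.30, "e2": 2.41, "neither": 0.89}


@dataclass
class BDSpec:
    """Parameters of one constructed disease."""

    e4_locus: int                      # carrier frequency ~0.147 in the source study
    e2_locus: int                      # ~0.076
    odds: dict = field(default_factory=lambda: dict(DEFAULT_BD_ODDS))
    precedence: str = "e4_over_e2"     # joint carriers fall in the e4 group
    seed: int = 0

    def __post_init__(self):
        if self.e4_locus == self.e2_locus:
            raise ValueError("the two BD loci must be distinct")
        for k in ("e4", "e2", "neither"):
            if not self.odds.get(k, 0) > 0:
                raise ValueError(f"odds[{k!r}] must be positive")


def assign_status_for_groups(groups: Sequence[str], odds: dict,
                             seed: int = 0) -> np.ndarray:
    """Control/case labels from genotype-group control/case odds.

    Each individual is labelled control with probability o/(1+o) for its
    group's control/case odds ``o``, independently across individuals.
    Returns a boolean *case* indicator.
    """
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    p_control = np.array([odds[g] / (1.0 + odds[g]) for g in groups])
    return rng.random(groups.size) >= p_control


def carrier_groups(store: GenotypeStore, ids: Sequence[int],
                   spec: BDSpec) -> np.ndarray:
    """Genotype group per individual: ``e4`` (>=1 minor allele at the
    e4-like locus; takes precedence), else ``e2``, else ``neither``."""
    ids = np.asarray(ids, dtype=int)
    stats = minor_allele_stats(store, ids)
    for locus in (spec.e4_locus, spec.e2_locus):
        if not stats.defined[locus] or stats.maf[locus] == 0:
            raise ValueError(f"BD locus {locus} is monomorphic in the sample set")
    codes = store.dense_codes(ids, [spec.e4_locus, spec.e2_locus]).astype(float)
    carrier = np.zeros_like(codes, dtype=bool)
    for j, locus in enumerate((spec.e4_locus, spec.e2_locus)):
        col = codes[:, j]
        if stats.mfa_is_alt[locus]:
            carrier[:, j] = col >= 1            # >=1 alternate allele
        else:
            carrier[:, j] = (col == 0) | (col == 1)  # >=1 reference allele
    groups = np.full(ids.size, "neither", dtype=object)
    if spec.precedence == "e4_over_e2":
        groups[carrier[:, 1]] = "e2"
        groups[carrier[:, 0]] = "e4"
    else:
        groups[carrier[:, 0]] = "e4"
        groups[carrier[:, 1]] = "e2"
    return groups


def assign_bd_status(store: GenotypeStore, ids: Sequence[int],
                     spec: BDSpec) -> tuple[np.ndarray, np.ndarray]:
    """BD case indicator (and genotype group) for each individual."""
    groups = carrier_groups(store, ids, spec)
    is_case = assign_status_for_groups(groups, spec.odds, seed=spec.seed)
    return is_case, groups


def ascribe_bd_age(is_case: np.ndarray, groups: np.ndarray,
                   reference_ages: dict, seed: int = 0) -> np.ndarray:
    """Age of diagnosis for BD cases by inverse-CDF sampling.

    Each case draws from the empirical cumulative distribution of its
    genotype group's reference ages (linear interpolation between order
    statistics); sampled ages therefore lie within the reference range.
    Non-cases receive NaN.
    """
    is_case = np.asarray(is_case, dtype=bool)
    groups = np.asarray(groups)
    for g in np.unique(groups[is_case]):
        if g not in reference_ages or len(reference_ages[g]) == 0:
            raise ValueError(f"no reference ages for genotype group {g!r}")
    rng = np.random.default_rng(seed)
    ages = np.full(is_case.size, np.nan)
    for g in np.unique(groups[is_case]):
        mask = is_case & (groups == g)
        u = rng.random(int(mask.sum()))
        ages[mask] = np.quantile(np.asarray(reference_ages[g], dtype=float),
                                 u, method="linear")
    return ages


def bd_metadata(store: GenotypeStore, ids: Sequence[int], spec: BDSpec,
                reference_ages: Optional[dict] = None,
                control_age_mean: float = 86.1,
                control_age_sd: float = 6.0) -> list[SampleRecord]:
    """Full BD phenotype table compatible with the main pipeline.

    Case ages come from the group-conditional empirical CDFs; control
    ages (age at last visit, not disease-linked) are drawn from a normal
    distribution.  Cohort labels are inherited as a single BD cohort when
    the caller does not re-assign them.
    """
    ids = np.asarray(ids, dtype=int)
    is_case, groups = assign_bd_status(store, ids, spec)
    if reference_ages is None:
        # age shifts mirroring the protective/risk roles of the two groups
        reference_ages = {
            "e4": np.linspace(62, 82, 201),
            "e2": np.linspace(70, 90, 201),
            "neither": np.linspace(66, 86, 201),
        }
    ages = ascribe_bd_age(is_case, groups, reference_ages,
                          seed=spec.seed + 1)
    rng = np.random.default_rng(spec.seed + 2)
    ctrl_ages = rng.normal(control_age_mean, control_age_sd, ids.size)
    records = []
    for i, row in enumerate(ids):
        age = ages[i] if is_case[i] else max(ctrl_ages[i], 40.0)
        records.append(SampleRecord(
            sample_id=store.sample_ids[row], cohort="BD",
            status="case" if is_case[i] else "control", age=float(age)))
    return records


def bd_null_validation(store: GenotypeStore, ids: Sequence[int], spec: BDSpec,
                       n_targets: int = 12, n_reps: int = 3,
                       config: Optional[NetConfig] = None,
                       top_k: int = 20, seed: int = 0) -> dict:
    """Run the downstream pipeline on one BD and report burden-age GLMs.

    Evaluates ``n_targets`` randomly chosen tSNPs off the BD chromosome,
    splits them by mCVt sign into provisional protective/risk sets, and
    regresses each case's (raw and CVt-weighted) burden on the ascribed
    age of BD diagnosis.  Because BD status is independent of every locus
    except the two defining ones, the headline expectation is
    non-significant slopes.
    """
    from .burden import burden_counts, glm_slope_test
    from .engine import derive_seed, evaluate_tsnp

    ids = np.asarray(ids, dtype=int)
    records = bd_metadata(store, ids, spec)
    is_case = np.array([r.status == "case" for r in records])
    ages = np.array([r.age for r in records])

    # balance by status (single BD cohort)
    rng = np.random.default_rng(derive_seed(seed, "bd-balance"))
    case_rows, ctrl_rows = ids[is_case], ids[~is_case]
    n_bal = min(case_rows.size, ctrl_rows.size)
    bal = np.concatenate([rng.choice(case_rows, n_bal, replace=False),
                          rng.choice(ctrl_rows, n_bal, replace=False)])
    bal_labels = np.concatenate([np.ones(n_bal, bool), np.zeros(n_bal, bool)])

    bd_chroms = {store.loci[spec.e4_locus].chromosome,
                 store.loci[spec.e2_locus].chromosome}
    off_chrom = [i for i, l in enumerate(store.loci)
                 if l.chromosome not in bd_chroms]
    targets = np.random.default_rng(derive_seed(seed, "bd-targets")).choice(
        off_chrom, size=min(n_targets, len(off_chrom)), replace=False)

    results = [evaluate_tsnp(store, bal, bal_labels, int(t), n_reps=n_reps,
                             config=config, top_k=top_k, seed=seed)
               for t in targets]
    protective = {r.locus_index: abs(r.mcvt) for r in results if r.mcvt < 0}
    risk = {r.locus_index: abs(r.mcvt) for r in results if r.mcvt > 0}

    case_ids = ids[is_case]
    case_ages = ages[is_case]
    report = {"spec": spec, "n_targets": len(results), "glm": {}}
    for name, weights in (("protective", protective), ("risk", risk)):
        if not weights:
            continue
        counts = burden_counts(store, case_ids, weights, weighting="none")
        weighted = burden_counts(store, case_ids, weights, weighting="cvt")
        for label, x in ((f"{name}_count", counts), (f"{name}_weighted", weighted)):
            if np.ptp(x) > 0:
                fit = glm_slope_test(x, case_ages)
                report["glm"][label] = fit
    return report
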