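"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

import netsnp as ns


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort for plumbing tests: 600 samples x 400 loci, the two
    APOE-like planted loci plus one strong rare risk locus."""
    planted = (
        ns.PlantedEffect(locus=0, maf=0.147, control_case_odds=0.30,
                         tag="risk", gene="E4LIKE"),
        ns.PlantedEffect(locus=1, maf=0.076, control_case_odds=2.41,
                         tag="protective", gene="E2LIKE"),
        ns.PlantedEffect(locus=2, maf=0.05, control_case_odds=0.25,
                         tag="risk", gene="RARERISK"),
    )
    spec = ns.SynthSpec(n_samples=600, n_snps=400, planted_effects=planted,
                        seed=11)
    store, records, manifest = ns.generate_cohort(spec)
    return store, records, manifest


@pytest.fixture(scope="session")
def engine_cohort():
    """Cohort with strong planted effects for netSNP engine tests:
    1,200 samples x 300 loci, strong common risk and protective loci."""
    planted = (
        ns.PlantedEffect(locus=0, maf=0.15, control_case_odds=0.25,
                         tag="risk", gene="RISK1"),
        ns.PlantedEffect(locus=1, maf=0.15, control_case_odds=3.5,
                         tag="protective", gene="PROT1"),
    )
    spec = ns.SynthSpec(n_samples=1200, n_snps=300, planted_effects=planted,
                        seed=23)
    store, records, manifest = ns.generate_cohort(spec)
    return store, records, manifest


@pytest.fixture(scope="session")
def engine_balanced(engine_cohort):
    """Balanced rows/labels of the engine cohort."""
    store, records, _ = engine_cohort
    retained = ns.filter_cohorts(records)
    keep = [r for r in records if r.cohort in retained]
    idx = {s: i for i, s in enumerate(store.sample_ids)}
    rng = np.random.default_rng(5)
    cases = [r.sample_id for r in keep if r.status == "case"]
    controls = [r.sample_id for r in keep if r.status == "control"]
    n = min(len(cases), len(controls))
    ids = (list(rng.choice(cases, n, replace=False))
           + list(rng.choice(controls, n, replace=False)))
    rows = np.array([idx[s] for s in ids])
    labels = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
    return store, rows, labels


@pytest.fixture(scope="session")
def fast_net_config():
    return ns.NetConfig(hidden_layers=(16, 8), max_epochs=150, seed=0)


@pytest.fixture(scope="session")
def apoe_cohort():
    """Cohort for the two-locus genotype-assignment experiment: APOE-like
    planted loci with per-allele (dose-dependent) odds, as for real APOE."""
    planted = (
        ns.PlantedEffect(locus=0, maf=0.147, control_case_odds=0.30,
                         tag="risk", gene="E4LIKE", model="dosage"),
        ns.PlantedEffect(locus=1, maf=0.076, control_case_odds=2.41,
                         tag="protective", gene="E2LIKE", model="dosage"),
    )
    spec = ns.SynthSpec(n_samples=3000, n_snps=300, planted_effects=planted,
                        seed=41)
    return ns.generate_cohort(spec)


@pytest.fixture(scope="session")
def balance_records():
    """Helper: status-balanced rows/labels over retained cohorts."""
    return _balance_records


def _balance_records(store, records, seed=5):
    retained = ns.filter_cohorts(records)
    keep = [r for r in records if r.cohort in retained]
    idx = {s: i for i, s in enumerate(store.sample_ids)}
    rng = np.random.default_rng(seed)
    cases = [r.sample_id for r in keep if r.status == "case"]
    controls = [r.sample_id for r in keep if r.status == "control"]
    n = min(len(cases), len(controls))
    ids = (list(rng.choice(cases, n, replace=False))
           + list(rng.choice(controls, n, replace=False)))
    rows = np.array([idx[s] for s in ids])
    labels = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
    return rows, labels
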