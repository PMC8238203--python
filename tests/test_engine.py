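"""netSNP engine: genotype assignment, tSNP scoring, null calibration."""

import numpy as np
import pytest

import netsnp as ns
from netsnp.engine import APOE_CODE_PAIRS


def _scaling(ncols):
    return ns.FeatureScaling(lo=np.zeros(ncols), hi=np.full(ncols, 2.0))


def test_assign_genotype_locality_and_identity():
    rng = np.random.default_rng(0)
    sc = _scaling(4)
    x = sc.apply(rng.integers(0, 3, size=(20, 4)).astype(float))
    out = ns.assign_genotype(x, 2, 2, sc)
    assert np.array_equal(np.delete(out, 2, axis=1), np.delete(x, 2, axis=1))
    assert np.all(out[:, 2] == 1.0)          # code 2 on a 0..2 scale -> +1
    # assigning the code every row already holds is the identity
    x2 = x.copy(); x2[:, 1] = -1.0           # everyone code 0
    assert np.array_equal(ns.assign_genotype(x2, 1, 0, sc), x2)
    assert not np.shares_memory(out, x)


def test_assign_genotype_commutes_across_columns():
    rng = np.random.default_rng(1)
    sc = _scaling(3)
    x = sc.apply(rng.integers(0, 3, size=(10, 3)).astype(float))
    ab = ns.assign_genotype(ns.assign_genotype(x, 0, 2, sc), 1, 1, sc)
    ba = ns.assign_genotype(ns.assign_genotype(x, 1, 1, sc), 0, 2, sc)
    assert np.array_equal(ab, ba)
    with pytest.raises(IndexError):
        ns.assign_genotype(x, 5, 1, sc)
    with pytest.raises(ValueError):
        ns.assign_genotype(x, 0, 3, sc)


@pytest.fixture(scope="module")
def planted_results(engine_balanced, fast_net_config):
    store, rows, labels = engine_balanced
    out = {}
    for locus in (0, 1):   # planted risk (odds 0.25) and protective (3.5)
        out[locus] = ns.evaluate_tsnp(store, rows, labels, locus, n_reps=3,
                                      config=fast_net_config, top_k=20, seed=31)
    return out


def test_planted_risk_locus_scores_positive(planted_results):
    res = planted_results[0]
    assert res.mcvt > 0
    assert all(float(np.mean(a)) > float(np.mean(n))
               for a, n in zip(res.alt, res.nat))


def test_planted_protective_locus_scores_negative(planted_results):
    assert planted_results[1].mcvt < 0


def test_dif_is_alt_minus_ref_and_sign_coherent(planted_results):
    for res in planted_results.values():
        for a, r, d in zip(res.alt, res.ref, res.dif):
            assert np.array_equal(d, a - r)
        assert np.sign(res.mean_dif) == np.sign(res.mcvt - res.mean_nat)
        assert -0.5 <= res.mcvt <= 0.5
        assert res.n_reps == 3


def test_evaluate_tsnp_deterministic(engine_balanced, fast_net_config):
    store, rows, labels = engine_balanced
    r1 = ns.evaluate_tsnp(store, rows, labels, 5, n_reps=2,
                          config=fast_net_config, top_k=20, seed=42)
    r2 = ns.evaluate_tsnp(store, rows, labels, 5, n_reps=2,
                          config=fast_net_config, top_k=20, seed=42)
    assert r1.mcvt == r2.mcvt
    assert all(np.array_equal(a, b) for a, b in zip(r1.nat, r2.nat))


def test_evaluate_tsnp_target_out_of_store(engine_balanced, fast_net_config):
    store, rows, labels = engine_balanced
    with pytest.raises(IndexError):
        ns.evaluate_tsnp(store, rows, labels, store.n_loci + 3,
                         config=fast_net_config)


def test_target_never_duplicated_in_features(engine_balanced, fast_net_config, monkeypatch):
    """When the target would rank in the top 49, the feature set still
    holds 50 distinct loci with the target exactly once."""
    store, rows, labels = engine_balanced
    seen = {}
    import netsnp.engine as eng
    orig = eng.train_patternnet

    def spy(x_train, y_train, x_val, y_val, cfg, feature_loci=(), scaling=None, **kw):
        seen["loci"] = list(feature_loci)
        return orig(x_train, y_train, x_val, y_val, cfg,
                    feature_loci=feature_loci, scaling=scaling, **kw)

    monkeypatch.setattr(eng, "train_patternnet", spy)
    ns.evaluate_tsnp(store, rows, labels, 0, n_reps=1,
                     config=fast_net_config, top_k=20, seed=3)
    loci = seen["loci"]
    assert len(loci) == 20
    assert loci.count(0) == 1
    assert len(set(loci)) == 20


def test_apoe_assignment_identity_and_ordering(apoe_cohort, balance_records):
    """Assigned two-locus genotypes order the mean CV as e22 < e23 <
    {e33, e24} < e34 < e44 (protective to risk)."""
    store, records, _ = apoe_cohort
    rows, labels = balance_records(store, records, seed=7)
    labels = labels.astype(int)
    # features: the protective (e2-like) and risk (e4-like) loci first
    feature_loci = [1, 0] + list(range(2, 20))
    perm = np.random.default_rng(8).permutation(len(rows))
    rows, labels = rows[perm], labels[perm]
    split = int(0.8 * len(rows))
    cfg = ns.NetConfig(hidden_layers=(20, 8), max_epochs=250, seed=0)
    x_train, scaling = ns.build_feature_matrix(store, rows[:split], feature_loci)
    x_val = scaling.apply(store.feature_codes(rows[split:], feature_loci))
    net = ns.train_patternnet(x_train, labels[:split], x_val, labels[split:],
                              cfg, feature_loci=feature_loci, scaling=scaling)
    x_hold = scaling.apply(store.feature_codes(rows[split:], feature_loci))
    means = {g: float(np.mean(ns.apoe_genotype_assignment(net, x_hold, 0, 1, g)))
             for g in APOE_CODE_PAIRS}
    assert means["e22"] < means["e23"] < min(means["e33"], means["e24"])
    assert max(means["e33"], means["e24"]) < means["e34"] < means["e44"]
    with pytest.raises(ValueError):
        ns.apoe_genotype_assignment(net, x_hold, 0, 99, "e33")
    with pytest.raises(ValueError):
        ns.apoe_genotype_assignment(net, x_hold, 0, 1, "e55")


def test_null_band_validation_and_classification():
    band = ns.NullBand(mcvts=np.linspace(-0.1, 0.1, 101), alpha=0.05,
                       n_random=101, seed=0, n_reps_per_target=5)
    assert band.lower < 0 < band.upper
    mk = lambda locus, m: ns.TSnpResult(locus, [np.zeros(1)], [np.zeros(1)],
                                        [np.full(1, m)], [np.full(1, m)],
                                        mcvt=m, dispersion=0.0, n_reps=1,
                                        mfa_is_alt=True)
    results = [mk(0, -0.4), mk(1, 0.0), mk(2, 0.4)]
    classes = ns.classify_tsnps(results, band)
    assert classes["protective"] == [0]
    assert classes["indeterminate"] == [1]
    assert classes["risk"] == [2]
    assert classes["p_empirical"][0] < 0.05 < classes["p_empirical"][1]
    with pytest.raises(ValueError):
        ns.classify_tsnps([], band)


def test_null_band_input_validation(engine_balanced, fast_net_config):
    store, rows, labels = engine_balanced
    with pytest.raises(ValueError, match="at least 100"):
        ns.null_band_mcvt(store, rows, labels, n_random=10,
                          config=fast_net_config)
    with pytest.raises(ValueError, match="exceeds"):
        ns.null_band_mcvt(store, rows, labels, n_random=store.n_loci + 1,
                          config=fast_net_config)


def test_derive_seed_stable_and_bounded():
    s1 = ns.derive_seed(1, "stage", 0)
    assert s1 == ns.derive_seed(1, "stage", 0)
    assert s1 != ns.derive_seed(1, "stage", 1)
    assert 0 <= s1 < 2 ** 31
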