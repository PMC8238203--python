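# netsnp

Neural-network permutation-importance scoring of genetic variants in
polygenic case/control cohorts.

Genome-wide association tests score each SNP marginally and miss rare
variants and variants whose effect is expressed through interactions.
`netsnp` takes the complementary route: train a feed-forward
pattern-recognition network to classify cases against controls from
individual genotypes, then probe the *trained, frozen* network one SNP at
a time — artificially assign every holdout individual the homozygous
minor-allele genotype at a target SNP (tSNP) and measure how the
classifier value distribution shifts. The package targets exome-scale
case/control studies such as late-onset Alzheimer's disease cohorts and
ships everything needed to run and audit the procedure on synthetic data
with known ground truth.

## Method

Genotypes are coded 0 (hom. reference), 1 (het.), 2 (hom. alternate),
−1 (missing) and held sparsely. After dropping cohorts whose minority
class is under 20% of the majority (or with < 20 individuals), training
sets draw equal cases and controls per cohort, so training prevalence is
exactly 0.5. Each SNP gets a two-sided Fisher's exact p-value (FishP) on
its 2×2 table of (minor, reference) allele counts in (cases, controls);
the 50 lowest-FishP SNPs feed a `patternnet`-style network (hidden
layers 50 and 10, softmax head) trained full batch by scaled conjugate
gradient (cross-entropy with weight-decay ratio 0.1; maxEpochs = 1000,
minGrad = 1e−6, maxFails = 10, σ = 5e−5, λ = 5e−7). The network emits a
classifier value CV = P(case) − 0.5 ∈ [−0.5, +0.5] per individual.

For a target SNP *t*, each of 20 repetitions redraws a ~70% training
subset of a balanced set, re-ranks SNPs, trains on *t* plus the 49
best-ranked others, and records holdout scores NAT (true genotypes),
REF (*t* forced homozygous non-minor), ALT (*t* forced homozygous minor)
and DIF = ALT − REF. The mean ALT score over individuals × repetitions,
**mCVt**, is the tSNP's importance weight: mCVt < 0 marks a protective
minor allele, mCVt > 0 a risk allele. Significance is calibrated against
the empirical mCVt distribution of randomly chosen target SNPs, and the
calls are validated by regressing per-individual tSNP burden (raw and
|mCVt|-weighted minor-allele dosage) on age of diagnosis and Braak
stage. Constructed-disease simulations — status re-assigned from two real
loci with fixed control/case odds (0.30 / 2.41 / 0.89) — provide the
negative control for linkage and pipeline bias.

## Worked example

```python
import numpy as np
import netsnp as ns

spec = ns.default_spec(seed=1)                     # 6,000 x 10,000 synthetic cohort
store, records, truth = ns.generate_cohort(spec)
retained = ns.filter_cohorts(records)
split = ns.balanced_split(records, retained, n_train=3200, n_holdout=1500, seed=1)

idx = {s: i for i, s in enumerate(store.sample_ids)}
by_id = {r.sample_id: r for r in records}
rows = lambda ids: np.array([idx[s] for s in ids])
y = lambda ids: np.array([by_id[s].status == "case" for s in ids]).astype(int)

ranked, assoc = ns.rank_snps(store, rows(split.train_ids),
                             y(split.train_ids).astype(bool), top_k=50)
x_train, scaling = ns.build_feature_matrix(store, rows(split.train_ids), ranked)
x_val = scaling.apply(store.feature_codes(rows(split.validation_ids), ranked))
net = ns.train_patternnet(x_train, y(split.train_ids), x_val,
                          y(split.validation_ids), ns.NetConfig(seed=1),
                          feature_loci=ranked, scaling=scaling)
x_hold = scaling.apply(store.feature_codes(rows(split.holdout_ids), ranked))
cv = net.predict_cv(x_hold)
labels = y(split.holdout_ids)
print("holdout accuracy:", round(ns.accuracy(cv, labels), 1), "%")
print("AUC:", round(ns.roc_curve(cv + 0.5, labels).auc, 3))

bal = np.concatenate([rows(split.train_ids), rows(split.validation_ids)])
bal_y = np.concatenate([y(split.train_ids), y(split.validation_ids)]).astype(bool)
cfg = ns.NetConfig(hidden_layers=(30, 10), max_epochs=300, seed=1)
for locus, name in ((0, "E4LIKE"), (1, "E2LIKE")):
    res = ns.evaluate_tsnp(store, bal, bal_y, locus, n_reps=5, config=cfg, seed=1)
    print(f"{name}: mCVt = {res.mcvt:+.3f} +/- {res.dispersion:.3f}")
```

prints

```
holdout accuracy: 64.7 %
AUC: 0.695
E4LIKE: mCVt = +0.295 +/- 0.029
E2LIKE: mCVt = -0.200 +/- 0.040
```

The classifier separates cases from controls well above chance on unseen
individuals, and netSNP recovers the planted effects with the right
signs: forcing everyone homozygous for the E4-like risk allele shifts
the mean CV strongly toward "case" (+0.295), the E2-like protective
allele toward "control" (−0.200).

A `netsnp` console command mirrors the stages (`synth`, `compress`,
`balance`, `train`, `score`, `simulate-bd`, `run`); see `netsnp --help`.

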