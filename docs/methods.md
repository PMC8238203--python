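# Methods

## The model

`netsnp` treats variant scoring as a feature-importance question about a
trained polygenic classifier. A feed-forward pattern network — tanh
hidden layers (default 50 and 10 units) and a softmax head — maps an
individual's genotype codes at 50 SNPs to a probability of being a case.
The classifier value CV = P(case) − 0.5 lives on [−0.5, +0.5], with
−0.5 the confident-control end and +0.5 the confident-case end.

Training is full-batch scaled conjugate gradient (SCG): conjugate
directions whose curvature term is estimated by a forward difference of
the gradient along the search direction (step `wt_sigma`/|p|), with a
Levenberg–Marquardt-style regulator λ adapted from the comparison
parameter Δ (raised when the quadratic model fits poorly, lowered when
it fits well), restarting to steepest descent every *W* iterations
(*W* = number of parameters). No line search is needed, which is what
makes SCG cheap per epoch. The performance function is

    perf = (1 − reg) · mean cross-entropy + reg · mean(w²),

with biases excluded from the penalty and `reg = 0.1` by default.
Training stops at `max_epochs` (1000), when the gradient norm falls
below `min_grad` (1e−6), or after `max_fails` (10) consecutive epochs of
rising validation performance; the weights of the best validation epoch
are returned. λ is clamped to [1e−15, 1e15] and the search direction is
reset to the gradient if it degenerates — numerical guards, not part of
the statistical model. Weight initialisation is scaled-uniform
(±√(6/(fan_in+fan_out))) from the config seed; a (seed, data) pair fully
determines the trained network.

Genotype features are the codes {0,1,2} with missing (−1) mapped to 0 —
the sparse-default semantics of an exome VCF, where absence means
homozygous reference. Each feature is affinely mapped to [−1, 1] by its
training-set min/max (constant features to 0); holdout values outside
the training range are clipped. The CV output scaling (−0.5, 0.5) is an
output convention, distinct from this input scaling.

## The netSNP score

For a target SNP (tSNP), each repetition: (1) draw a fresh ~70%
case/control-stratified training subset of a balanced sample set;
(2) re-rank all SNPs by two-sided Fisher's exact p (FishP) on
allele-count tables from that subset; (3) train on the tSNP plus the 49
best-ranked *other* SNPs (if the tSNP itself ranks in the top 49, the
next-ranked SNP fills the matrix rather than duplicating it); (4) score
the held-out ~30% with true genotypes (NAT), with the tSNP forced
homozygous for the non-minor allele (REF), and forced homozygous for the
minor frequency allele (ALT); DIF = ALT − REF. When the minor allele is
the *reference* allele, ALT forces code 0 and REF forces code 2 — the
semantics follow the minor allele, not the alternate allele. mCVt is the
mean ALT score over individuals × repetitions; its dispersion is the
standard error of per-repetition means. Repetition *r* of target *t*
derives its seed from (master seed, *t*, *r*), so evaluations are
independent and replayable. The holdout is redrawn each repetition by
default; a fixed-holdout mode exists because either protocol is
defensible.

Significance is empirical: mCVt for `n_random` uniformly chosen target
SNPs forms a null sample; a tSNP is protective/risk when its mCVt falls
below/above the α/2 and 1−α/2 quantiles, with a rank-based two-sided
empirical p. Random targets use fewer repetitions (default 5 versus 20)
for tractability; the band object records this.

## Fisher's exact test

FishP uses allele-level counting (two chromosomes per individual,
missing genotypes excluded from both margins) and the point-probability
two-sided rule: sum hypergeometric probabilities of all tables with the
observed margins whose probability does not exceed the observed table's
(relative slack 1e−12 so exact ties survive floating point). Because
rare loci have tiny hypergeometric support, the whole locus panel is
evaluated in one vectorised enumeration, grouped by support width; the
implementation is tested against exact rational enumeration.

## Cohort structure and balancing

Multi-site consortia mix cohorts with very different case:control
ratios, and a genotype classifier can exploit cohort signatures
(platform artifacts) instead of disease signal — a 50-SNP network can
identify cohort membership far above the ~4% chance floor of 24 cohorts.
Cohorts with fewer than 20 individuals or a minority class under 20% of
the majority are dropped; training partitions take equal cases and
controls within every retained cohort (prevalence exactly 0.5).
Validation (default 15% of the training pool) is balanced the same way.
The holdout is *not* forced to 0.5 by default, since it stands for
evaluation data; a balanced-holdout mode reproduces the accuracy
protocol on balanced data. Because real prevalence is far below 0.5,
metrics include a prevalence sweep: per-class error rates are measured
once, then the confusion matrix is reweighted analytically to each
target prevalence (a resampling cross-check mode exists); thresholds are
either fixed at CV = 0 (zero predicts control — zero is not positive) or
placed at the cost-optimal operating point, the first ROC point touched
by a line of slope S = (Cost(P|N)−Cost(N|N))/(Cost(N|P)−Cost(P|P))·N/P
slid down-right from (0, 1).

## Constructed diseases and burden validation

A constructed disease (BD) re-labels a genotyped population from two
chosen loci whose carrier frequencies match APOE ε4 (~0.147) and ε2
(~0.076): E4-like carriers become controls with odds 0.30, E2-like
carriers with odds 2.41, everyone else with odds 0.89. Carrier means at
least one minor allele (the three-way odds don't distinguish het/hom);
joint carriers fall in the E4 group, since the odds triple does not
cover the joint case. Ages of BD diagnosis are drawn by inverse-CDF
sampling from each genotype group's empirical reference distribution.
Since a BD is linked only to its two defining loci, any burden-vs-age
correlation found off the BD chromosome indicates method bias; the
headline expectation of the BD pipeline run is non-significance.

Burden is minor-allele dosage (0/1/2, missing = 0, orientation taken
from the population minor allele) summed over a tSNP set, optionally
weighted by |mCVt| — set membership already encodes direction, so the
weight is a magnitude. Slope tests are ordinary least squares with an
F-test of the slope on (1, n−2) degrees of freedom (equal to the squared
t statistic). Expected signs: protective burden correlates positively
with age of diagnosis and negatively with Braak stage; risk burden the
opposite.

## The synthetic cohort generator

The generator emulates the *structure* of a large exome consortium, not
its population genetics: per-locus binomial genotype draws from a
rare-skewed frequency mixture (96% of loci uniform on MAF 0.001–0.008,
the rest a common tail on 0.02–0.35, so ≥95% of loci land below MAF 0.01
after sampling noise), optional copy-based LD blocks, 24 cohorts (half
balanced, a quarter case-heavy, a quarter control-heavy — enough to
exercise the filter), 0.2% missing calls, and planted effect loci.
Disease status follows the same genotype-conditional odds mechanism as
the BD simulator, multiplicative in log-odds around the 0.89 baseline so
single-locus carriers reproduce their configured group odds exactly.
Planted effects are dominant ("carrier") by default, matching the BD
mechanism; a per-allele ("dosage") mode exists for APOE-like loci,
because real APOE acts dose-dependently and the two-locus
genotype-assignment experiment needs that gradation. Default planted
loci are an E4-like risk locus (MAF 0.147, odds 0.30), an E2-like
protective locus (0.076, 2.41), and eight graded loci (MAF 0.05, odds
3.0/2.41/2.0/1.5 protective and 0.33/0.41/0.5/0.67 risk) for sign- and
rank-recovery evaluation; 0.05 gives enough carriers at desk-scale
sample sizes for a classifier to see rare-but-testable effects.

Case ages are baseline 75.4 y shifted −8.4 y per planted risk allele and
+3.8 y per protective allele (the magnitudes APOE shows per allele) with
Gaussian noise (sd 8 y); control ages centre on 86.1 y (age at last
visit) and carry no genetic signal. Braak stages discretise a latent
burden-plus-noise variable through increasing thresholds; only a
configurable autopsy fraction (default 0.28) receives one. What the
generator does **not** emulate: linkage beyond declared blocks,
population stratification within cohorts, genotyping error structure,
sex or ancestry covariates. Passing tests therefore demonstrate that the
machinery recovers known effects under clean conditions, not that it is
robust to every real-data confound.

## Numerical and design choices

- Two-sidedness of Fisher's test is the point-probability convention,
  oracle-backed; other conventions (doubling) would change FishP for
  asymmetric tables.
- The `reg` parameter is a MATLAB-style performance *ratio*:
  (1−reg)·CE + reg·mean(w²).
- CV = P(case) − 0.5 reconciles 0/1 labels with the ±0.5 CV scale; the
  [0,1] score is used for ROC analysis.
- Ranking ties (equal FishP) break by (chromosome, position) so runs are
  reproducible.
- Loci with undefined MAF in a training subset are dropped from ranking
  with a logged count; all-missing loci never reach the feature matrix.
- The empirical-band α uses standard two-tail quantiles (α/2, 1−α/2);
  α → 0 degenerates to the full (min, max) range of the null sample.
- The on-disk `.nss` store is a gzip text container (JSON header plus
  one locus/sample/code triplet per stored entry, fixed mtime) so
  serialisation is lossless and byte-stable for replay checks.
- Multi-allelic VCF records are skipped with a warning; pre-splitting
  with an external normaliser is the supported path.

## Problem sizes in the test suite

Unit tests run on cohorts of 300–1,200 individuals with small networks.
The recovery suite uses 6,000 × 10,000 cohorts with 5 repetitions per
tSNP and a (30, 10) network capped at 300 epochs; the null-calibration
suite uses an 800 × 1,000 cohort with a 100-SNP random band at 2
repetitions per target. These are the package's desk-scale defaults for
simulation studies; repetition counts and network size scale up
unchanged for production runs (20 repetitions, (50, 10), 1000 epochs).

## Known limitations

- mCVt from few repetitions is noisy; rank agreement between effect size
  and |mCVt| is reliable for the seed-averaged score, less so per seed.
- The empirical null band inherits Monte-Carlo error from `n_random`;
  with 100 random targets the band quantiles themselves wobble by a few
  percent.
- The generator's independence assumption makes Fisher ranking stronger
  than it would be under LD; planted-effect recovery rates on synthetic
  data are therefore optimistic bounds.
- K-class heads (used for the cohort-identity check) share the training
  machinery but not the CV convention, which is strictly binary.
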