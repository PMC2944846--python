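# Methods

## The model

`snplca` clusters individuals from additively coded biallelic SNP
genotypes (0 = major homozygote, 1 = heterozygote, 2 = minor
homozygote, minor allele defined in the control group) with a latent
class model: a finite mixture of independent per-SNP multinomials.
Individual *i* belongs to unobserved class *k* with probability
π<sub>k</sub>, and conditional on the class its genotype at SNP *j* is
category *g* with probability θ<sub>kjg</sub>, independently across
SNPs.  The observed-data log-likelihood is

    ℓ = Σ_i log Σ_k π_k Π_{j ∈ obs(i)} θ[k, j, g_ij]

where obs(*i*) is the set of SNPs observed for individual *i*.  Missing
genotypes are marginalized out under a missing-at-random assumption —
they contribute no factor, so individuals with missing genotypes remain
in the analysis; an individual with every genotype missing contributes
log Σ π<sub>k</sub> = 0 and its posterior equals the prior π.
Individuals are assigned to the class with the highest posterior
membership probability (ties to the lowest class index).

## EM fitting

The E-step computes responsibilities by Bayes' rule over observed
entries only; the M-step sets π to mean responsibilities and θ to
responsibility-weighted category frequencies among individuals observed
at each SNP.  Numerical choices:

- **Log space.** All per-individual products over dozens of SNPs are
  accumulated as sums of logs (via one-hot matrix products), so
  underflow cannot occur.  A true zero probability is represented by a
  large negative constant; if an individual ends up with zero
  probability under every class, the likelihood is reported as −∞ with
  a warning, never an exception.
- **Smoothing.** ε = 1e−10 is added to M-step category counts.  This
  keeps every θ strictly positive so that models fitted on one dataset
  never assign −∞ to another (essential for bootstrap replicates).
  The distortion (~1e−10 in probability) is far below every tolerance
  used anywhere in the package.
- **Multi-start with short runs.** Starts are random responsibility
  matrices (Dirichlet(1) rows; default 20 starts).  Every candidate
  runs a 25-iteration burn-in and only the best by log-likelihood is
  refined to convergence: relative log-likelihood change < 1e−8 or
  2,000 iterations.  The log-likelihood is non-decreasing within every
  run (a property the tests assert on every recorded trace).
- **Warm starts.** `em_fit` accepts extra initial parameter values.
  Nested fits exploit this: a (k+1)-class fit can start from a k-class
  solution with its largest class split in two (the twin perturbed 5%
  toward a random simplex point to break symmetry).  Warm starts only
  add candidates to the start pool; they never replace the random
  starts.

## Choosing the number of classes

The number of latent classes is selected by a stepwise parametric
bootstrap likelihood-ratio test.  For k = 1, 2, …: fit k and k+1
classes, form LR = 2(ℓ<sub>k+1</sub> − ℓ<sub>k</sub>), draw B datasets
(default 20) from the *fitted* k-class model with per-SNP missingness
re-imposed at the observed per-SNP rates (an option replicates the
exact entry-level pattern instead), refit both models on each
replicate, and estimate p = (1 + #{LR\* ≥ LR}) / (B + 1).  Selection
stops at the first k with p ≥ α (default 0.05); if every test up to
k_max rejects, k_max is returned with a warning.  Because the p-value
estimator only reaches 1.0 when every replicate beats the observed
statistic, α ≥ 1 is short-circuited to "accept k = 1 without testing".
Note the estimator's floor is 1/(B+1): at α = 0.05 the test can only
reject when B ≥ 20.

Two optimizer details matter for the test's behavior, and both were
adopted after measuring their failure modes at cohort scale
(875 × 46):

1. **Replicate refits are warm-started** from the generating null model
   (for k) and from its split-class perturbation (for k+1).  With
   purely random starts, roughly one replicate k-fit in twenty landed
   ~150 log-likelihood units below its optimum, injecting a spurious
   right-tail outlier into the null LR distribution — and a single
   outlier at B = 20 moves p from 0.048 to 0.095.
2. **Replicate refits use the same EM settings as the observed fits**
   (overridable).  The bootstrap compares the observed statistic to
   replicates produced by an identical procedure; when the observed
   fits were allowed more starts and tighter tolerances than the
   replicates, the observed overfit gain at the true k systematically
   exceeded the replicate distribution and the procedure overshot k.

Cluster flow between successive models (the joint cross-tabulation of
assignments under k and k+1 classes) is exact counting; its marginals
reproduce both models' cluster sizes and its total is always n.

## Explanation trees and forests

Clusters are explained from genotypes by CART-style recursive binary
partitioning with *categorical subset* splits: a node sends a subset of
{0,1,2} left (e.g. "genotype 1 and/or 2"), chosen by exhaustive
enumeration of the ≤ 3 candidate bipartitions per SNP to maximize the
root-scaled Gini decrease (n_obs/n_root) · (impurity drop), evaluated
over individuals observed at that SNP.  Growth stops at purity, below
`min_split` (default 20) individuals, or when the best decrease falls
below `cp` (default 0.01) times the root impurity — every accepted
split therefore satisfies decrease ≥ cp · root impurity.  Ties break
toward the lower SNP index and the earlier canonical subset, making
growth deterministic.  There are no surrogate splits: individuals
missing the genotype at a decision SNP are excluded from that split's
evaluation and from deeper nodes, and at prediction time an individual
missing any *visited* decision genotype is returned as UNALLOCATED.
The drop-down report (correct / misclassified / unallocated against the
model-based assignment) always partitions the cohort.

The random forest bags these trees: bootstrap samples of individuals,
`mtry` (default ⌊√m⌋) random candidate features per node, grown to
purity.  It reports the out-of-bag (OOB) misclassification rate of each
individual's OOB majority vote, permutation importance (mean OOB
accuracy drop after permuting a feature; exactly 0 for constant
features), and mean decrease in Gini impurity.  Categorical features
may contain missing values, which become an extra category; numeric
features (threshold splits at midpoints) must be complete — the
pipeline imputes clinical variables by mode (binary/categorical) or
median (age) first.

## Canonical discriminant analysis and MANOVA

CDA solves the generalized eigenproblem B v = λ W v (between- vs pooled
within-cluster scatter of the coded genotypes, mean-imputed per SNP for
this stage only).  Axes are scaled so each canonical variable has unit
pooled within-group variance, and scores are centered at the derivation
sample's overall mean — derivation-sample canonical means are therefore
zero to floating-point noise (~1e−16), and the reported standard
deviations combine the unit within-group variance with between-group
spread.  A singular within-group scatter receives a ridge of
1e−8 · trace(W)/m with a warning.  Axis signs are fixed by making each
axis's largest-magnitude coefficient positive.

A second population is projected through the derivation rule unchanged
(same centering, same coefficients).  The canonical means of the two
populations on the first two axes are compared by Wilks' Λ =
det(E)/det(E+H) with Rao's F approximation, which is exact for two
groups (and equivalent to Hotelling's T²; the tests verify this
algebraically and against an independent MANOVA implementation).

In the pipeline, a group whose chosen model has fewer than three
classes defines fewer than two canonical axes; the missing axes are
padded with leading principal components of the within-cluster
residual, scaled to unit pooled within variance, so projection and the
MANOVA comparison remain defined even in the degenerate single-cluster
configuration.

## Association statistics

Each cluster is tested against all other clusters on each binary
clinical trait in a 2×2 table; individuals with a missing trait value
are excluded and counted.  Statistics: OR = ad/bc; the Woolf interval
exp(ln OR ± 1.96 √(1/a + 1/b + 1/c + 1/d)) (any zero cell triggers the
Haldane–Anscombe +0.5 correction, flagged); Pearson chi-square without
continuity correction, n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) on 1 df; and a
Fisher exact p whenever some expected cell count is below 5.  No
multiple-testing correction is applied to the primary columns — these
are exploratory contrasts — but Bonferroni and Benjamini–Hochberg
adjusted p-values are appended as supplementary columns.  Multivariable
analysis is a backward-elimination logistic regression (maximum
likelihood via iteratively reweighted least squares): clusters passing
a univariate screen at p < 0.1 enter, and the predictor with the
largest Wald p above the removal threshold (default 0.10) is dropped
until all survivors satisfy it.  Collinear designs and (quasi-)perfect
separation raise an explicit error naming a predictor involved.

## The synthetic cohort generator

The generator is the package's test bed: each individual draws a class
from the group's mixing proportions, genotypes independently per SNP
from that class's 3-category profile, missingness per entry (MCAR) at
per-SNP rates, and binary phenotypes from class-conditional prevalences
(phenotypes are independent of genotypes given the class).  Profiles
can be specified directly or derived from per-class minor-allele
frequencies under Hardy–Weinberg proportions.

The **paper-scale preset** mirrors a published candidate-SNP cohort's
structure: 875 cases in 6 classes with mixing proportions taken from
that cohort's reported cluster sizes, 367 controls in 5 classes
(mixing 0.30/0.25/0.20/0.15/0.10), 46 SNPs, 2% per-entry missingness
(the reported 6.6% of cases missing at least one of three decision
SNPs implies ≈2% per SNP), and per-class clinical prevalences equal to
the published per-cluster percentages.  Class genotype profiles use a
*signature-block* construction: all classes share a baseline MAF drawn
once from U(0.08, 0.20) per SNP (a fixed design constant, not a data
seed), and each class's round-robin block of ~m/k SNPs is raised to
MAF 0.45.  This guarantees every class pair differs at ~2m/k SNPs
(minimum pairwise symmetric KL ≈ 14.5 nats).  The guarantee matters:
the null distribution of the bootstrap LR at this scale spans roughly
160–195 (cases) and 140–165 (controls) from overfitting alone, so any
class pair whose merge costs less log-likelihood than that is
statistically invisible at B = 20 — iid-drawn profiles produce such
near-duplicate pairs by chance.  The SNP panel is synthetic; it is not
the published marker panel.

The **3-class recovery design** (n = 2,000, 6 SNPs, equal mixing, 5%
missingness) uses two non-Hardy–Weinberg profiles, a major-homozygote
baseline (0.85, 0.10, 0.05) and a minor-homozygote signature
(0.05, 0.10, 0.85).  Keeping every category probability far from 0.5
caps the sampling standard error of each estimated θ entry at ≈0.014,
so the sup-norm parameter-recovery check at tolerance 0.05 reflects
estimation quality rather than binomial noise (with Hardy–Weinberg
profiles the heterozygote category sits near 0.5 and sampling noise
alone breaches 0.05 for a substantial fraction of seeds at this n).

What the generator deliberately does *not* emulate: linkage
disequilibrium between SNPs, Hardy–Weinberg departures in real cohorts,
population stratification, genotyping error, informative (non-MCAR)
missingness, and phenotype–genotype dependence beyond the latent class.
Passing tests therefore demonstrate that the algorithms recover the
structure they assume, at realistic sample sizes and missingness — not
that real cohorts satisfy those assumptions.

## Problem sizes used by the test suite and acceptance script

Chosen so the full battery runs comfortably on a single CPU: likelihood
oracles on ≤ 6×3 instances; parameter recovery at n = 2,000; LRT null
calibration over 20 runs at n = 500, m = 10, B = 20; forest checks at
n = 500 (planted) and n = 1,000 (chance level); and cohort-scale
class-count recovery over 10 seeds (test suite) or 6 seeds (acceptance
script) at the full 875/367 × 46 scale with B = 20.

## Known limitations

- Only categorical (genotype) variables enter the latent class model;
  mixed continuous/categorical modeling is not implemented.
- Class membership does not depend on covariates (no latent class
  regression), and the number of classes is chosen solely by the
  stepwise bootstrap LRT (no information criteria).
- The bootstrap interprets the null-model simulation parametrically;
  with B = 20 the p-value granularity is 1/21, so α much below 0.05
  requires a larger B.
- VCF ingestion is restricted to biallelic records; no genotype QC
  (call-rate filters, Hardy–Weinberg tests) or imputation is performed
  at load time.
- The CDA stage mean-imputes missing genotypes; an alternative using
  posterior membership probabilities as inputs is available but the
  genotype route is the default.
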