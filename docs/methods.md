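# Methods

## The MIC contrast test

For a bivariate sample D of size n, the maximal information coefficient is

    MIC(D) = max_{x·y < B(n)}  I*(D, x, y) / log min(x, y),

where I*(D, x, y) is the largest mutual information achievable by any grid
that partitions the x-axis into x bins and the y-axis into y bins, and
B(n) = n^exponent bounds the grid size.  Both the mutual information and the
normaliser use base-2 logarithms; the ratio is base-invariant, but fixing
the base keeps intermediate values comparable across the code and tests.
The default exponent is 0.8, which works well for genotype data (the
general-purpose MIC literature often uses 0.6; both are supported).  For
ternary genotype data any bound above 9 is equivalent, since no grid beyond
3×3 can increase I*.

Only cut points placed between consecutive distinct values change the
induced cell distribution, so for alphabets of at most 6 distinct values the
optimiser enumerates *every* cut-point subset and the score is exact.
Richer or continuous variables — outside the epistasis workflow — are
searched over a pool of at most 11 rank-equipartition candidate cut points;
that path is an approximation, traded for bounded cost.

Conventions for degenerate inputs: a constant axis admits no 2-bin
partition, and such pairs score MIC = 0 (independence is the only
defensible reading).  Requesting more bins than an axis has distinct values
silently evaluates the largest feasible partition, which keeps
nearly-monomorphic SNPs from raising spurious errors.  Samples too small
for B(n) to admit a 2×2 grid (n^0.8 ≤ 4, i.e. n ≤ 5) are a configuration
error.

The epistasis statistic for a SNP pair is ΔMIC = |MIC_all − MIC_case| /
MIC_all.  The case subset is fixed by design — controls are assumed
recruited independently of the interaction, so the case stratum is the
informative one; a controls-only variant is deliberately not offered.  When
MIC_all ≤ 1e−12, or either column is monomorphic, no contrast is
interpretable: ΔMIC is defined as 0, the p-value as 1, and the pair flagged
`degenerate`.

## Permutation scheme

The null distribution of ΔMIC comes from shuffling the labels while
preserving the case count n₂.  ΔMIC depends on a shuffle only through the
case-stratum 3×3 contingency table, and under a uniform random size-n₂
subset those nine cell counts follow a multivariate hypergeometric
distribution on the pooled pair table.  The implementation therefore draws
the counts directly (`Generator.multivariate_hypergeometric`) — an exact
reformulation of label shuffling, not an approximation — and evaluates the
batch of 3×3 tables vectorised.  MIC_all is computed once per pair; label
permutation cannot change it.

The p-value is count/m with "≥" counting ties against significance, so
p = 0 is attainable and p always lies on the grid {0, 1/m, …, 1}.  A
`conservative` option reports (count+1)/(m+1) instead; it is off by
default.  The default m = 1000 resolves p down to 0.001, below the
strictest significance level (0.005) used in pathway-scale scans.  Each
pair's RNG seed is a hash of the master seed with the *sorted* pair of SNP
identifiers, and the hypergeometric category order is fixed by a canonical
orientation of the pooled table, so scans are bit-reproducible regardless
of column order or parallelisation, and swapping the two SNPs changes
nothing but the id ordering.  Rows with a missing genotype in either column
are dropped pairwise, which preserves the per-pair MIC definition.

Multiplicity: the scan reports raw permutation p-values; beyond choosing a
working α (e.g. 0.005), correction for the number of pairs is left to the
caller.

## Simulated disease models

A two-locus model is a 3×3 penetrance table f(g_A, g_B) with Hardy-Weinberg
genotype frequencies at each locus and independent loci.  Prevalence is
K = Σ P(g)f(g); heritability uses the broad-sense form
h² = Σ P(g)(f(g) − K)² / (K(1 − K)), the convention of the GAMETES family
of simulators from which the model taxonomy here derives.

* **Null models** are parameterised as odds tables (baseline odds γ; the
  marginal-recessive variant multiplies one homozygous-minor row by 1+θ)
  and converted cell-wise via f = o/(1+o).  With γ = 1 the baseline
  penetrance is 0.5, which is inconsistent with any fixed population
  prevalence parameter; null-model runs are therefore treated as balanced
  case-control draws from the odds-implied penetrances and ignore the
  prevalence setting.
* **Marginal-effect (ME) models** are six published 3×3 tables stored
  verbatim; the prevalence implied by each table under HWE reproduces its
  printed value to three decimals (asserted in the tests).
* **Pure/strict (NME) models** have all six per-locus marginal penetrances
  equal to K, so the pair carries interaction signal only — the hardest
  detection regime.  Generation draws a Gaussian 3×3 deviation table,
  projects it onto the equal-marginals constraint by HWE-weighted double
  centering (the exact projection under the P⊗P inner product), rescales
  deviations to hit the target h² exactly, and accepts when all cells land
  in [0, 1].  Accepted models satisfy |h² − target| ≤ 1e−6 and marginal
  deviations ≤ 1e−9 (in practice both hold to machine precision);
  infeasible (h², MAF, K) triples raise after a bounded number of tries.
  This search strategy is this package's own; only the constraint set is
  inherited from the pure/strict definition.

## Dataset sampling

Balanced case-control datasets fill exact n/2 quotas per stratum.
Marginalising the generative scheme "draw genotypes under HWE, draw status
Bernoulli(f(g)), keep until quotas fill" gives the case stratum the Bayes
conditional P(g)f(g)/K and the control stratum P(g)(1−f(g))/(1−K); the
sampler draws stratum cell counts from those conditionals directly, which
is distributionally identical and constant-time in the rejection rate.
Goodness-of-fit of both strata against the conditionals is asserted in the
tests.  An unascertained mode (status ~ Bernoulli(f)) exists for cohort
draws; population prevalence influences ascertained sampling only through
the strata conditionals.

Each dataset carries two functional SNPs (`P1`, `P2`, always the first two
columns) and p_total − 2 noise SNPs drawn i.i.d. under HWE, independent of
phenotype.  The default layout is 10 SNPs.  The noise-SNP MAF defaults to
the functional-locus MAF so that noise pairs are marginally
indistinguishable from the functional pair; it is configurable.  What the
generator does **not** emulate: linkage disequilibrium between SNPs (a
known false-positive source for a dependence-based statistic — nearby SNPs
in strong LD are dependent in every stratum), genotyping error, missing
data patterns, population stratification, and >2-locus models.  Passing
simulation tests therefore demonstrate calibration and power under
independent-SNP architectures, not robustness to LD; on real data,
intra-gene (and ideally intra-LD-block) pairs should be filtered, as the
`filter_significant` gene-map option supports.

## Experiment harness

A replicate simulates one dataset and runs the permutation test on the
designated functional pair; success is p ≤ α (α = 0.05 by default).  Power
(or type-I error, under a null model) is m₁/replicates with its binomial
standard error.  The "designated pair" decision — rather than requiring a
whole-scan discovery rule over all 45 pairs — is the reading consistent
with null rejection rates near α; a `scan_all` mode (success requires the
functional pair significant *and* top-ranked) exists for sensitivity
analysis.  The marginal-model type-I scenario likewise tests the marginal
SNP against a null SNP.  Replicate seeds derive from
SeedSequence(master, index), so grids are order-independent and resumable;
NME cells can average over several independently generated models, each
with its own model seed and replicate stream.

For the 1k–5k sample-size trend, fresh datasets are drawn per size (a
per-replicate pool with subsampling would induce dependence across sizes
without changing the marginal distribution of each estimate).

## Problem sizes and tolerances in the shipped checks

The acceptance pipeline uses 100 replicate null datasets (n = 3,000,
m = 1,000) for the type-I check and 5 models × 50 replicates (n = 4,000,
m = 1,000) per power cell; the package's own choice of desk-scale replicate
counts keeps the full recomputation under a minute while leaving binomial
uncertainty (±2 SE ≈ ±0.04 on a rate near 0.05, smaller near power 1)
well inside the comparison bands used.  Type-I calibration is judged
against the exact binomial 99% band; power cells against the published
values with slack for model-regeneration variance, since regenerated
pure/strict models match the published ones in distribution, not
identically.  Property tests pin the exact-optimiser claim to a scalar
brute-force oracle on small ternary samples, and the hypergeometric
permutation path to a literal label-shuffle oracle.

## Known limitations

* ΔMIC is undirected evidence of case-specific dependence; it does not
  estimate an interaction effect size or orientation.
* LD is not modelled or corrected for (see above); the statistic will
  flag strong LD blocks.
* The relative contrast is unstable when MIC_all is near zero; the
  degenerate guard handles exact zeros, but very small MIC_all still
  inflates ΔMIC's scale.  The permutation null shares this scale, which is
  what keeps the test calibrated.
* The continuous-variable MIC path is approximate and untuned; the package
  is built for ternary genotype data.
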