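# Methods

`rvliab` implements a rare-variant liability analysis for sex-stratified
trio (and duo / case-control) cohorts: exact-binomial burden and
transmission tests on count data, conversion of enrichment into
liability-scale effect sizes under a sex-specific liability threshold
model, covariate-matched gene-set permutation nulls, fixed-effect
meta-analysis with multiplicity tiers, and a generative cohort simulator
that makes every stage verifiable by parameter recovery without access
to any controlled dataset.

## The liability threshold model

A latent liability is assumed additive and normally distributed in the
population; a person is affected when their liability exceeds a
threshold fixed by the trait prevalence in their sex.  With a male
prevalence `K_m = 2.5%` (1 in 40) and a male:female prevalence ratio of
4:1 (`K_f = 0.625%`), the thresholds are `T_m = Phi^-1(1-K_m) = 1.96`
and `T_f = 2.50` standard deviations.  Under this *different-threshold*
model females need a larger liability load to be diagnosed, which is
the mechanism the simulator and the analytic sex-ratio predictions
exercise.  An unequal-variance variant (male liability variance 2-3x
the female) is supported: thresholds and effects are computed under
`N(0, sigma_sex^2)` and reported both raw and rescaled to the
standardized scale.  Phenotype subgroups (autistic probands with
co-occurring motor/cognitive impairment) get scaled prevalences:
the observed subgroup fraction times the sex prevalence (e.g.
35% x 2.5% = 0.88% for impaired males), with the complement assigned to
the remaining probands.

## Liability-scale effect sizes

The effect size `z` of a variant class is the mean liability shift of
carriers relative to the population.  From per-sample variant rates in
cases and controls, the carrier penetrance follows by Bayes' rule under
a rare-carrier approximation:

    P(affected | carrier) = r_case K / (r_case K + r_control (1 - K))

(valid for rates well below ~0.1 per sample; the code warns beyond
that).  The default estimator then inverts the threshold model:

    z = T - Phi^-1_upper(penetrance)

i.e. the shift that gives a normally distributed carrier group exactly
the observed penetrance.  Correctness is anchored to simulation
recovery: under the generative model this inversion returns the true
carrier shift exactly in the large-sample limit for a single-carrier
class.  A second convention — the penetrance-weighted mixture of the
affected/unaffected truncated-normal tail means,
`z = P*phi(T)/K - (1-P)*phi(T)/(1-K)` — is provided as
`method="mixture"` for comparison with analyses that used it.  It is
*attenuated*: at prevalence 2.5% it converges to 0.15 when the true
shift is 0.6, so it is not the default and is excluded from recovery
claims.

Two known limits of the rate-based inversion are documented and tested:

* **Multi-carrier attenuation.**  Counts, not carrier indicators, enter
  the rates; probands carrying two damaging variants (Poisson
  multiplicity) pull the large-sample limit slightly below the true
  per-allele shift — about -1% at `beta = 0.6` and -4% at `beta = 1.0`
  with a de novo rate of 0.02 per child (`asymptotic_liability_estimate`
  computes the limit for any configuration).
* **Standard errors.**  Following the published convention, the
  standard error is reconstructed from the exact binomial p-value of the
  case/control event split (`se = |z| / q`, `q` the two-sided normal
  quantile of p), and sex-difference contrasts use
  `z_f - z_m ± 1.96 sqrt(se_f^2 + se_m^2)`.  The symmetric Wald interval
  built from this `se` undercovers at large effects (the reconstruction
  uses the secant, not the tangent, of the rate-to-z map), so
  *count-based* estimates instead map the exact Clopper-Pearson interval
  on the event split through the monotone ratio -> penetrance -> z
  transform, inheriting the exact interval's coverage.  At `p = 1` (or
  `z = 0`) the `se` is undefined and reported missing with the Wald CI
  suppressed.

## Burden and transmission tests

Enrichment is a rate ratio: DNMs per proband over DNMs per sibling, or
transmitted over untransmitted parental alleles (null ratio 1, i.e.
transmission fraction 0.5).  Significance uses the two-sided exact
binomial test in the minimum-likelihood convention — the p-value sums
the probabilities of all outcomes no more likely than the observed one —
on the event split against the sample-size expectation
`n_case/(n_case+n_control)`.  The implementation delegates to
`scipy.stats.binomtest` and is pinned, in tests, to an exact-rational
enumeration oracle over all `n <= 25`.  Ratio CIs map the exact
Clopper-Pearson interval on the split through
`f -> f/(1-f) * n_control/n_case`.  Zero control counts give an
infinite ratio with a one-sided interval rather than a continuity
correction, since the exact test remains valid.  The one-sample
two-sided exact Poisson test used for mutational-model expectations
(`expected = 2 mu n_trios` under per-haploid rates; factor 1 if a rate
table is declared diploid) follows the same minimum-likelihood
convention and is written in-package (no installed equivalent).

Sex contrasts compare the female share of events to the female share of
samples (DNMs) or of parental alleles (transmission).  Parent-of-origin
burden compares mothers to fathers with parent counts, not allele
counts, as denominators.

## Meta-analysis and multiplicity

Cohort estimates combine by fixed-effect inverse-variance weighting:
rate ratios on the log scale with the log-se recovered from the CI
width, liability estimates on the z scale.  No heterogeneity statistics
are computed.  Families of tests are corrected by Bonferroni (family
size 54 for the exome-wide family: 3 sex comparisons x 3 cohorts x 3
variant classes x 2 inheritance modes; 108 for phenotype-stratified
families, configurable) and by Benjamini-Hochberg FDR, with tiers
`***`/`**`/`*` for significance after Bonferroni / after FDR / only
before correction.  When a partial family is adjusted against a larger
declared family size, BH values are capped at their Bonferroni
counterparts to preserve the tier ordering.

## Matched gene-set nulls

A tested gene set is gauged against 10,000 random same-size sets drawn
from the remaining genes, matched per target gene by exact LOEUF decile
and quantile bins (quintiles by default; configurable) of sex-averaged
brain expression and CDS length, drawn uniformly with replacement within
stratum (a drawn set may repeat genes).  Empty strata fall back to the
nearest stratum (same decile, then the whole pool), logged.  The
permutation-averaged rate ratio becomes the expected ratio of the exact
binomial test (`f0 = R n_case / (R n_case + n_control)`; transmission
`R/(1+R)`), and the permutation-mean proband rate replaces the sibling
rate in the excess-liability conversion.  Draws with a zero denominator
are dropped; if they exceed 1% of draws the ratio of summed counts
across all draws is used instead (logged).  All draws flow through
numpy's seedable PCG64 generator and the seed is recorded in the
summary; an exhaustive-enumeration twin (`enumerate_expected_ratio`)
serves as the oracle on tiny pools.

## QC and classification rules

Exclusions are phrased as strict inequalities, so passes are inclusive:
genotypes need `DP >= 10`, `GQ >= 10`, `VAF >= 0.25` (missing metrics
fail closed).  Rarity tiers: cohort and gnomAD MAF < 0.1% (absence from
gnomAD passes); ultra-rare duo variants are in exactly one family and
absent from gnomAD; ultra-rare case-control variants have AF < 0.005%.
Damaging PTVs are PTVs in genes at or below the configured LOEUF decile
(1 strict; 2-3 relaxed); damaging missense have MPC >= 2 (>= 1 relaxed).
Variants in genes missing from the metadata table classify as `other`
with a warning.  The maximal-unrelated selection greedily removes the
individual with most relatedness edges, breaking ties by removing a male
before a female and then by smaller identifier, so females are
preferentially retained.  Phenotype stratification offers the
two-group scheme (impaired vs not-impaired-or-unknown, IQ cutoff 70 by
default and exposed as a parameter, since cohort definitions mix IQ
cutoffs and diagnostic codes) and the three-group motor/cognitive scheme
(IQ < 80, cognitive impairment or motor delay -> impaired; explicit
"no" on everything -> not impaired; otherwise unclassified).  The
random-forest site filter, sample-outlier metrics and kinship inference
are upstream of the package's contract; it consumes pre-filtered tables
and declared relatedness pairs, and no VCF ingestion is provided.

## The cohort simulator

Each child draws a background liability `N(0, sigma_sex^2)` plus fixed
shifts `beta_class` per carried damaging allele.  Parents carry rare
heterozygous alleles per gene (per-class per-parent carrier rates,
default 0.05 / 0.15 / 0.50 for damaging PTV / damaging missense /
synonymous); children inherit each parental allele with probability
one half, recorded as transmitted/untransmitted rows for the proband.
De novo counts per class are Poisson with per-child means 0.02 / 0.06 /
0.30 (i.e. roughly 0.02 damaging-PTV DNMs per exome), assigned to genes
proportionally to per-gene rates; simulated damaging PTVs occur only in
decile-1 genes and damaging missense carry MPC 2.5, so classification
round-trips exactly.  Families are ascertained through an affected
proband by rejection sampling; one non-autistic sibling per family is
redrawn until unaffected; `duo` mode sequences only the mother,
`case_control` mode emits unrelated affected/unaffected individuals
without parents.  Fixed seeds reproduce cohorts bit-for-bit.

Co-occurring impairment is a second, higher threshold on the same
liability axis by default; since the mechanism is not identified by the
data the package also offers a correlated second axis
(`rho = 0.6` default) that shares the variant shifts.  Either way the
impairment threshold is calibrated analytically (root-finding on the
Poisson-mixture tail, bivariate normal for the correlated option) so
the impaired fraction among autistic probands hits the configured
targets, 0.35 in males and 0.40 in females.

For replicate studies (hundreds of cohorts of tens of thousands of
families) the simulator also exposes exact-conditional samplers: the
per-child damaging count given (un)affected status has the closed form
`P(k | affected) ∝ Poisson(k; lambda) * Phi_upper((T - beta k)/sigma)`,
so probands and siblings can be drawn directly from the conditional
law.  Conditioning is on proband status only, which is exactly what
rejection sampling conditions on, so estimator inputs are
distributionally identical; the equivalence is tested against the
table-level simulator.  These samplers support a single effective
(de-novo-only) variant class and refuse otherwise.

What the generator does **not** emulate: genome coordinates and
sequence context, linkage disequilibrium, common-variant background,
assortative mating, sex-chromosome inheritance, ancestry structure,
genotyping error and ascertainment quirks of real cohorts (e.g.
multiplex families, phenotype missingness patterns).  Passing
recovery tests therefore demonstrates internal consistency of the
estimators under the stated model, not robustness to these real-data
features.

## Problem sizes and numerical choices

Analysis drivers simulate 2,000-family cohorts with 200 genes; the
recovery study uses 200 replicates of 20,000 families (exact-conditional
path) at `beta = 0.6`; null calibration uses 2,000 replicates of
2,000-family cohorts, compared against the analytically computed exact
test size (slightly below 5% by discreteness); the headline sex-ratio
study uses 50,000-family cohorts over `beta in {0.3, 0.6, 1.0}`.
Thresholds come from `scipy`'s normal quantiles (agreement with a
root-find of the CDF to 1e-9 is tested); impairment calibration uses
Brent root-finding to 1e-8; permutation draws and cohort generation use
`numpy.random.default_rng` (PCG64) exclusively, with every consumed seed
recorded in outputs.  Degenerate inputs are signalled, not patched:
zero-event strata return NaN result rows, all-zero rates raise, p = 1
yields a missing se, and infeasible ascertainment raises after a bounded
retry budget.

## Known limitations

* The inversion estimator assumes normal carrier liability with a pure
  location shift; heterogeneous per-gene effects within a class are
  summarised by one average shift.
* The rare-carrier Bayes step ignores carrier frequency in the
  normalisation; it is accurate for rates well below 0.1 per sample.
* Sex-difference and meta CIs remain Wald-based (as published), so
  their coverage degrades for very large effects even though
  per-stratum CIs are exact-based.
* The greedy unrelated-set selection is a heuristic, not a maximum
  independent set; it matches the described procedure, including the
  preference for retaining females.
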