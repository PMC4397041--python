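# Methods

This package re-implements, as a tested pipeline, the quantitative analyses
used to characterise a contact zone between divergent stickleback ecotypes:
microsatellite diversity and differentiation, phenotypic-divergence P_ST and
its comparison with F_ST, Mendelian hybrid-cohort simulation, genotype-class
hybrid classification with a purity rule, and a hybrid-detection power
analysis.  Because the empirical genotype deposit is not available, every
stage is exercised end-to-end on a synthetic three-ecotype generator whose
structure mirrors the study system; all quantitative claims in the test suite
and the acceptance script are therefore statements about data generated under
stated conditions, recomputed at run time.

## Data model

Genotypes are diploid codominant microsatellite calls: unordered pairs of
integer fragment sizes, stored canonically smaller-first.  Missing data are
whole-genotype; a half-called genotype is demoted to missing with a warning,
because every estimator below assumes complete diploid calls.  Each
individual carries exactly one group label.  Markers belong to an explicit
panel (`neutral` or `qtl`); panel membership is biological knowledge supplied
by the user, never inferred.  GenePop (2- or 3-digit) is the interchange
format; output is always 3-digit.  Group labels are not part of GenePop, so a
sidecar TSV (individual, group) is the primary grouping channel, with the
leading prefix of the first individual id per POP block as a fallback.

## Diversity and Hardy-Weinberg tests

Observed heterozygosity H_O is the heterozygote fraction among typed
individuals.  Expected heterozygosity uses the small-sample correction
H_E = (2n/(2n-1)) (1 - sum_a p_a^2).  Two HWE tests are provided because
"exact chi-squared goodness-of-fit" conflates two families: a chi-squared
test of genotype counts against the expectations implied by the observed
allele frequencies (classes with expected count < 1 pooled into one "other"
class; df = classes - alleles, floored at 1), and a Monte-Carlo exact test
that permutes the 2n gene copies into random diploid pairings and scores the
chi-squared discrepancy, with the add-one correction
p = (1 + #{permuted >= observed}) / (1 + n_perm).  The Monte-Carlo test with
10,000 permutations is the default.  Monomorphic markers return p = 1 by
convention.  Bonferroni correction treats all tests supplied in one call as
the family.

## Differentiation statistics

**Weir-Cockerham theta.**  For every allele at every locus the three
variance components a (among populations), b (among individuals within
populations) and c (within individuals) are computed from group sizes, allele
frequencies and observed heterozygote-carry proportions, using the weighted
mean frequency, the n_c sample-size correction and the (r-1)-denominator
frequency variance of the 1984 moment estimator.  theta is the ratio of
summed components: per locus theta_l = sum_u a / sum_u (a+b+c), and the
multi-locus value is the ratio of sums over loci and alleles (never a mean of
ratios).  Loci with a zero denominator (monomorphic across the groups) are
excluded with a logged note; negative estimates are reported, not clamped, so
the bootstrap sees the estimator's true distribution.  The test suite holds
the implementation to an independently coded loop transcription of the
component formulas at 1e-12 on 200 random datasets.

**Jost's D.**  Per locus, with nh the harmonic mean group size and r groups:
H_S is the mean within-group gene diversity corrected by 2nh/(2nh-1); H_T is
the gene diversity of the unweighted mean allele frequencies plus the
matching H_S/(2 nh r) correction; D = [(H_T - H_S)/(1 - H_S)] * r/(r-1).
The multi-locus D averages the H_S and H_T components across loci before
forming the ratio (the behaviour of the widely used R estimator for this
statistic); a `mean_of_loci` switch averages per-locus D values instead.
Loci with H_S = 1, or monomorphic overall, are excluded with a note.

**Confidence intervals.**  Differentiation CIs are 95% percentile bootstrap
intervals over loci resampled with replacement (1000 replicates by default),
the standard unit for a multi-locus statistic; resampling individuals within
groups is available behind `boot_unit="individuals"`.  With a single
informative locus the interval degenerates to a point and is logged.
Pairwise matrices repeat the estimate for every unordered group pair and
also report the panel mean of pairwise values.

## P_ST and the P_ST-F_ST comparison

P_ST summarises phenotypic divergence of a heritable trait:

    P_ST = sigma2_GB / (sigma2_GB + 2 sigma2_GW)

with sigma2_GB the among-population and sigma2_GW the mean within-population
trait variance.  The general form carries a c/h^2 scalar on sigma2_GB; here
that scalar is 1 by default (the formula as used for lateral plate number, a
trait of high heritability) and is exposed as `scalar` for sensitivity
analyses.  Components come from a REML fit of the one-way random-intercept
model.  The fit profiles the restricted likelihood over the variance ratio
with a bounded 1-D optimisation; for balanced designs the closed-form ANOVA
method-of-moments solution (which REML reproduces exactly there) is used
directly, which matters because the bootstrap performs ~10^5 fits.  Negative
boundary estimates are truncated at zero and flagged.  A test pins the
profiled fit to the statsmodels MixedLM REML solution on unbalanced data.

P_ST confidence intervals are 95% percentile bootstrap over individuals
resampled with replacement within their own group (group sizes preserved),
1000 replicates; a degenerate replicate with no variance at all scores 0.
Pairwise P_ST refits the components on each group pair alone.

The P_ST-F_ST comparison vectorises matched pairwise values, computes
Pearson r, t = r sqrt(df)/sqrt(1-r^2) with df = pairs - 2, and a two-sided p
from the central t distribution — i.e. the six pairwise values are treated
as independent observations, exactly as the df = 4 of the four-group design
implies.  Fewer than four pairs, a constant vector, or |r| = 1 (t diverges)
are errors.  The long-format report canonicalises pair order so P_ST rows
and per-panel theta rows align, and yields one correlation row per panel.

## Hybrid-class simulation

Six genotype classes cover two generations of admixture — PA, PB, F1, F2,
BXA, BXB — characterised by ancestry-pair frequencies (phi_AA, phi_AB,
phi_BB): parents (1,0,0)/(0,0,1), F1 (0,1,0), F2 (1/4,1/2,1/4), backcrosses
(1/2,1/2,0)/(0,1/2,1/2).  Simulation is mechanistic rather than marginal:
F2 individuals are produced by mating two independently simulated F1
parents, each transmitting one of its two alleles chosen uniformly per
locus, and backcrosses mate a simulated F1 against a parental gamete.  The
marginal class frequencies are identical to drawing from the phi table, but
within-individual Mendelian sampling is preserved.  Loci are unlinked.  The
default cross design is 30 individuals in each of the four hybrid classes
plus parents, five replicates, each replicate on a sub-seed derived
deterministically from the master seed.

## Hybrid classification and admixture

The classifier is a deliberate plug-in-frequency simplification of the
Bayesian genotype-class samplers commonly used for hybrid detection: baseline
allele frequencies are point estimates smoothed with a 0.5 pseudo-count per
allele of the union allele universe (so no genotype has zero probability),
loci are unlinked, the class prior is uniform, and frequency uncertainty is
not integrated over.  Per locus, P({i,j}|class) mixes the Hardy-Weinberg
genotype probabilities of the three ancestry states with the class's phi
weights; log-likelihoods sum over non-missing loci, posteriors are softmax
with max-subtraction, and argmax ties break by the fixed class order PA, PB,
F1, F2, BXA, BXB.

The supervised admixture proportion q maximises the likelihood of the
per-copy mixture x_a = q p_a + (1-q) q_a over q in [0,1].  The log-likelihood
is concave in q, so the optimum is found by bisection on its derivative with
endpoint checks — deterministic, accurate to ~1e-15, returning exactly 0 or
1 at boundary optima, and antisymmetric under baseline swap to ~1e-9 (exact
antisymmetry is unattainable in floating point).  The purity rule keeps
individuals whose q toward their own labelled baseline is >= 0.9 (the
threshold is a parameter) and recomputes baseline frequencies from the kept
fish.

**Power analysis.**  Per replicate: purify both baselines, recompute
frequencies, simulate the cross design, classify every simulated individual,
and score per-class correct-assignment proportions; the report averages
across replicates and adds a summed confusion matrix, a coarse
parent-vs-hybrid dichotomy accuracy, and the purified baselines' multi-locus
theta.  One behaviour worth knowing: because simulated cohorts are drawn
from the same estimated baseline frequencies the classifier uses, two
*independent finite samples* of one population still yield accuracy slightly
above chance (the sampling noise in the frequency estimates is real signal
within the experiment).  The no-information limit — mean per-class accuracy
exactly 1/6 — is reached when the two baselines have identical estimated
frequencies, which is how the zero-divergence rung of the power checks is
constructed.

## Phenotype tools

Size correction is the common-within-group-slope ANCOVA convention: one
pooled within-group slope per trait, adjustment to the grand mean of the
size covariate.  This removes allometry without touching group mean
differences of size-independent traits (tested exactly for the b = 0 case).
Plate morphs are classed on mean plate number as low (<= 9), partial
(9, 29), complete (>= 29); the printed class limits overlap at 9, resolved
here to low, preserving the partial exemplar 10.5 and the complete floor 29.
The spine PCA runs on the covariance matrix of the (size-corrected) three
spine lengths (correlation optional); the first axis is the anti-predator
score PC_AP, sign-fixed so spine loadings are non-negative when they share a
sign.  Genotype-phenotype association is a one-way fixed-effects ANOVA with
R^2 = SS_between/SS_total and optional Tukey HSD post-hocs — a deliberate
simplification of the mixed-model trait tests of field datasets, whose R^2
values are therefore not comparable contract targets.  The HWE calculator
for expected phenotype-class fractions takes the penetrance map explicitly
(e.g. a recessive complete allele at frequency p gives p^2) rather than
assuming a dominance model.

## Synthetic data generator

Population allele frequencies follow the Balding-Nichols F-model: per locus
and population an independent Dirichlet draw with concentration
ancestral * (1-F)/F, giving expected differentiation ~ F; genotypes are drawn
in Hardy-Weinberg proportions within populations (a KS calibration test
checks that within-population HWE p-values are uniform).  F = 0 short-circuits
to exact copies.

The default scenario has three populations of 50 fish — two freshwater
residents and one anadromous — with nine neutral loci (6 alleles each) at
F = 0.12 and four QTL-linked loci (2-4 alleles) at F = 0.23, matching the
study's reported neutral and QTL-panel differentiation; QTL loci get fewer
alleles because the study's QTL markers were markedly less diverse than the
neutral panel.  A diallelic major plate locus (allele codes 240/172, the C
and L fragment sizes of the diagnostic plate marker) is fixed C in the
anadromous population and L in both residents.  Plate phenotype is major
locus + Gaussian polygenic modifier: CC fish get 31.5 +/- 0.8 plates (a
complete-morph distribution — the configured means are chosen so that class
membership is forced, not marginal), heterozygotes 29.5 +/- 1.0, LL fish a
per-population mixture — resident1 5 +/- 2 (low), resident2 an equal mixture
of 7 +/- 2 and 13 +/- 3, emulating plate variation among residents that the
major locus does not explain.  Linear traits (SL, BD, spines, gill-raker
length and count) take population-specific means echoing the reported
ecotype contrasts (anadromous SL 59 +/- 2 mm vs resident 39 +/- 5 mm;
gill-raker length 0.86 low / 1.26 complete), share an allometric slope on
centroid size, and the three spines load on a common latent factor tuned to
~0.95 shared variance so a single PCA axis carries nearly all spine variance.

`make_power_baselines` emits two populations on a 14-locus panel (the
study's panel size) at configurable F; the default F = 0.5 produces the
strongly divergent, near-diagnostic baselines of the power analysis, and
lower F values give the weaker rungs of a theta ladder.

What the generator does *not* emulate: microsatellite mutation (no stepwise
model, so allele-frequency geometry is Dirichlet-like rather than
ladder-like), linkage between QTL markers and the major locus, spatial or
salinity structure within populations, genotyping error and allelic dropout,
and landmark/shape data.  Passing tests therefore demonstrate correctness of
the estimators and pipeline under the stated generative conditions, not
robustness to those real-data complications.

## Numerical choices and problem sizes

All randomised operations take explicit seeds; sub-seeds derive from
`numpy.random.SeedSequence.spawn`, so identical seeds give byte-identical
outputs (the CLI writes with a fixed float format for this reason).  The
REML profile optimiser runs on log(lambda) in [-30, 15] with xatol 1e-10 and
an explicit boundary check at lambda = 0.  Percentile CIs use the 2.5/97.5
percentiles of finite replicates.  Recovery experiments in the tests and the
acceptance script use: 50 replicates of 200 loci x 3 populations x 50
individuals for F-recovery; 100 replicates of 3 x 50 with 1000-replicate
bootstraps for P_ST coverage (the analytic P_ST of fixed group means (-2, 0,
2) with unit within-group variance is 4/6); 10,000 individuals for Mendelian
proportion checks; and the default 30 x 5 cross design for classifier power.
These sizes make every experiment's Monte-Carlo error small relative to the
asserted bands while keeping a full run in minutes on one core.

## Known limitations

- The classifier ignores baseline-frequency uncertainty; with few baseline
  individuals its posteriors are overconfident relative to a full Bayesian
  treatment, and its power figures are an upper bound for panels whose
  frequencies are poorly estimated.
- Pairwise P_ST and theta values share groups, so treating the six pairwise
  values as independent in the correlation (as the df = 4 design implies) is
  anticonservative; a Mantel-style permutation would be the stricter test.
- One-way ANOVA in the association test ignores site-level structure; R^2
  from nested mixed models on field data will differ.
- Jost's D multi-locus combination follows the component-averaging
  convention; other software averages per-locus D and will disagree on
  heterogeneous panels.
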