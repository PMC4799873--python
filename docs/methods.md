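# Methods

## Data model

Every record is a single hemizygous X chromosome: males carry one allele
per X-linked locus, so each subject contributes one unambiguous haplotype
and no phasing is needed. Controls are likewise represented as one
chromosome each, matching per-chromosome denominators such as x/96.
Disease chromosomes are restricted to one per family (the first record per
`family_id`; extras are dropped with a warning), because related carriers
share the founder haplotype trivially.

Recombination fractions are derived from physical positions as
θ = |Mb distance to the mutation| × 0.01, i.e. 1 Mb ≈ 1 cM, clamped to
[0, 0.5]. No Haldane/Kosambi map function is applied: at the
sub-centimorgan distances of a founder region the map functions agree with
the linear rule to well below the precision of any downstream quantity,
and the rule keeps θ auditable from the map file. θ is always recomputed
from positions and never stored, so map and θ cannot drift apart.

Missing alleles (`NA`) are excluded pairwise: a chromosome missing marker
m leaves the counts at m only. Chromosomes with any missing allele are
excluded from haplotype grouping (a partial haplotype cannot be assigned);
the exclusion count is logged.

## Haplotype analysis

The ancestral haplotype is the marker-wise modal allele over complete,
unrelated disease chromosomes. Ties are broken toward the smallest
fragment length — an arbitrary but deterministic and reportable rule (the
bundled cohort has no ties). Any marker-wise modal vector minimises the
total mismatch count over the cohort, a property the test suite checks by
brute force.

Haplotype labels H1, H2, … are assigned by descending carrier count, then
lexicographic allele vector. For the bundled cohort this reproduces the
published H1–H3 but swaps the two of the three singleton labels that the
original report ordered by the carriers' geography; counts, frequencies
and mismatch classes are unaffected, and tests identify haplotypes by
allele vector rather than label.

## Association statistics

The difference in proportions uses the unpooled Wald form: z = 1.96,
SE = sqrt(p_D(1−p_D)/n_D + p_N(1−p_N)/n_N), no continuity correction; this
reproduces every published interval for the bundled cohort to its printed
precision. The two-sided Fisher exact p-value uses the minimum-likelihood
convention (sum of all tables with the observed margins whose point
probability does not exceed the observed one); the computation is
delegated to `scipy.stats.fisher_exact`, with an exhaustive hypergeometric
enumeration kept as an independent oracle in the tests. Alternative
two-sided conventions (doubling one tail) give different values and are
deliberately not offered.

δ = (p_D − p_N)/(1 − p_N) is always computed from exact count ratios,
never from rounded renditions. It is undefined when the allele is fixed in
controls (p_N = 1) and this is signalled as a distinct error. Published δ
confidence intervals for cohorts of this kind rarely state their method
and are not reproduced by scaling the Δp interval; we therefore report a
seeded nonparametric bootstrap CI (10,000 within-group resamples of
chromosomes, percentile method — for a single marker this is equivalent to
a binomial resample of the carrier count, which is how it is vectorised)
and make no claim of matching any published δ interval. No
multiple-testing correction is applied across markers; the per-marker
tests are reported as-is.

## Two-point LOD

Unrelated disease chromosomes are scored against the ancestral allele:
carriers are "nonrecombinant", others "recombinant", as if each extant
chromosome were one meiosis from the founder. This is a deliberate
simplification of a pedigree likelihood — it ignores identity by state and
the shared genealogy within the lineage — but it is the standard desk
calculation for founder cohorts of unrelated hemizygotes and is what the
package reproduces. LOD(θ) = NR·log₁₀(1−θ) + R·log₁₀θ + (NR+R)·log₁₀2 is
strictly concave on (0, 0.5) with the analytic maximum θ̂ = R/(NR+R)
(clamped to [0, 0.5]); the reported curve uses a 0.01 grid, and LOD(0.5)
is exactly 0 by construction. Conventional thresholds (evidence for
linkage above 3, against below −2) are exposed as constants.

Marker clusters: tightly linked intragenic markers can be treated as one
locus by maximising the *sum* of member LOD curves at a shared θ.
Summing curves is algebraically identical to pooling counts, so
θ* = ΣR/Σ(NR+R) and, for identical members, the cluster maximum is the
member count times the single-marker maximum. The alternative convention —
scoring the cluster once as a single marker — gives a three-fold smaller
score; the summed convention is the one used in founder-effect reports of
this kind and is labelled in the output.

## Allele age

Under per-generation decay at rate (1−θ), E[δ] after g generations is
(1−θ)^g, inverted by the moment estimator ĝ = log δ / log(1−θ). Because
an exponentially growing lineage is mostly young, ĝ systematically
underestimates the founder age; the Luria–Delbrück-style correction adds
−(1/r)·ln(θ·f·r) generations with the product f·r taken as 1/r, i.e.
−(1/r)·ln(θ/r), where r is the per-generation growth rate. The corrected
age is the *sum* of the two terms. This additive reading is the unique
one that reproduces both worked examples in the bundled cohort's
literature from their printed δ and θ; the report prints both terms
separately so the correction is auditable. Note the correction is
negative wherever θ > r (distal markers) and dominates wherever θ ≈ 0
(intragenic markers at < 0.1 cM); such rows are still printed, but only
markers with θ between roughly r/10 and r yield interpretable ages.

Calibrators: r = ln(T1/T0)/g_demo from census sizes T0, T1 separated by
g_demo generations (defaults reproduce r ≈ 0.03 for Italy: 3M at the
5th century BCE to 60M today over 100.48 generations of 25 years); the
sampled fraction f = sampled / (male population × incidence × mutation
share), e.g. 24 / (28M × 1/5000 × 7.6%) ≈ 0.06. Years are generations ×
years_per_generation (default 25).

One published position table lists the distal marker's *distance* column
equal to its absolute position (a transcription slip that would put it
154.86 Mb from a mutation it flanks at 0.73 Mb); the package always
derives θ from positions, which both sidesteps the slip and reproduces
the published age at that marker.

## Founder simulator

The generator emulates exactly the process the estimators assume, so that
parameter recovery is a meaningful check of the estimation chain rather
than of the generator:

- a single founder chromosome carrying the mutation (trajectory starts at
  1);
- a branching process: each carrier leaves Poisson(e^r) copies per
  generation. Runs in which the lineage dies out, or ends smaller than
  the requested sample, are restarted (up to 1000 times, from the same
  seeded stream, so results stay a deterministic function of the config):
  the real cohort is ascertained as having at least that many carriers
  today;
- a carrying capacity `max_population` (default 10,000): beyond it a
  uniform random subset survives. This bounds time and memory for large
  g; it leaves every per-lineage recombination probability untouched, so
  founder-allele retention remains (1−θ)^g;
- recombination per transmission, either independently per marker with
  probability θ_m (`per_marker_independent` — the estimator's own model),
  or via crossover points from a Poisson process on a genetic map scaled
  by the inverse Haldane transform d_m = −ln(1−2θ_m)/2 so that the
  marginal odd-crossover probability to marker m is exactly θ_m
  (`haldane_map` — correlated replacement along each flank). Every
  transmission may recombine; restricting recombination to female meioses
  (X linkage) would only rescale g, and the estimators make the same
  per-generation simplification;
- replacement alleles and control chromosomes drawn i.i.d. from
  per-marker background spectra (linkage equilibrium); defaults can be
  fitted from any control table, including the packaged one;
- optional stepwise slippage mutation (one repeat unit up/down per event),
  default off.

Features of real data deliberately not emulated: diploid female carriers,
selection, population structure and migration, marker ascertainment, and
linkage disequilibrium within the background pool. Passing recovery tests
therefore demonstrates correctness of the estimation chain under the
model's own assumptions, not robustness to these violations.

Seeding: replicate k of any experiment uses
`SeedSequence([seed, k])` (31-bit), so experiments are reproducible and
trivially parallelisable.

A subtlety the validation suite makes explicit: (1−θ)^g is the
identity-by-*descent* retention probability. If the founder allele also
segregates in the background pool, identity-by-state exceeds it (replaced
alleles can be re-drawn as the founder length), so retention checks use
background spectra without the founder allele. Similarly, the whole
lineage shares its earliest meioses; at small r this genealogical
correlation skews the sampling distribution of δ̂ so that the *median*
age estimate sits below the truth even though the mean bias is ≈ 0 (we
measured mean bias between −1 and +4 generations for r from 0.17 to 0.8
at g = 50). Recovery checks therefore run at r ≥ 0.3, i.e. rapid founder
establishment, where δ̂ concentrates near its expectation.

## ABC age posterior

MCMC-based Bayesian allele-age software is treated as out of scope (its
internal model is not reproducible from the available description); in
its place the package offers rejection ABC on the simulator: uniform
prior over a grid of candidate ages, summary statistic the per-marker δ̂
vector (computed against the hypothesised founder haplotype in both the
observed and simulated cohorts, keeping the comparison symmetric and free
of per-iteration re-inference; undefined entries count as 1), acceptance
when the Euclidean distance is within a tolerance, credible interval from
posterior quantiles over the grid. Validation is property-based:
self-consistency (the interval covers the generating age) and empirical
coverage — at the default validation scale (two markers at 1 and 3 cM,
24 case / 48 control chromosomes, grid 10–100 by 10, 60 simulations per
point, tolerance 0.25) the nominal 95% interval covered the truth in
39/40 seeded trials, against an acceptance floor of 85% that acknowledges
grid and tolerance coarseness. Zero acceptances raise an error advising a
larger tolerance rather than returning a degenerate posterior.

## Problem sizes used in the validation suite

Chosen as the package's own validation scale: retention, 400 replicates
of n = 500 at g = 93, θ = 0.0073; recovery, 200 replicates of n = 200 at
g = 50, θ = 0.01, background without the founder allele; ABC coverage, 40
trials at the scale above. All headline cohort statistics are exact desk
calculations on 120 chromosomes and run in milliseconds.

## Degenerate inputs and tie-breaks (summary)

- modal-allele ties → smallest fragment length;
- label ties among equal counts → lexicographic allele vector;
- δ with p_N = 1 → distinct error; δ ≤ 0 → age undefined, row dropped
  from age tables (flagged in recovery experiments);
- LOD at θ = 0 with R > 0 → −∞; θ̂ clamped to [0, 0.5];
- Fisher with a zero margin → error;
- simulator extinction → seeded restart, then a distinct error naming the
  attempt count; sample larger than the surviving lineage → error
  suggesting larger g or r.
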