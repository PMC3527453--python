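# Methods

## Candidate exposures

A biallelic SNP coded by variant-allele count admits exactly four binary
risk indicators — the order-respecting splits {0}, {0,1}, {1,2}, {2} —
i.e. dominant and recessive codings of either allele; splits that break
the genotype ordering ({0,2} vs {1}) are not candidates.  A binary
polymorphism (gene deletion scored present/null) admits its two levels.
A k-way combination is a conjunction of indicators on distinct
polymorphisms.  The closed-form candidate count
Σ_j C(n_snps, k−j)·4^(k−j)·C(n_binary, j)·2^j is cross-checked in the
test suite against the materialised enumeration; with 6 SNPs + 1 binary
polymorphism it gives 26, 288 and 1,760 candidates at k = 1, 2, 3.

With allele-string input ("G/T") the counted allele is the minor allele
estimated from control chromosomes, ties broken alphabetically.  The
orientation only relabels indicators (each split's complement is also
enumerated), so scan results do not depend on it.

## Scoring and ranking

Each candidate is scored from its 2×2 exposure-by-status table with the
crude OR, Woolf CI on the log scale, the Wald statistic
(ln OR)²/(1/a+1/b+1/c+1/d) referred to χ²(1), and Bonferroni adjustment
with the per-(order, stratum) candidate count as denominator.

Numerical choices:

- **Zero cells**: Haldane–Anscombe (+0.5 to all four cells) whenever any
  cell is zero.  Tables with an entirely empty margin (in practice: no
  exposed subject in either group) have no meaningful OR even after
  correction; they are excluded from the ranking and logged.
- **Missing genotypes**: complete-case per combination — a subject is
  dropped from a combination's table iff a member genotype is missing.
- **Tie-breaking**: ranking ties break by larger |ln OR|, then by the
  lexicographic combination key, making scans bit-reproducible and
  invariant to subject row order and polymorphism column order.
- **Ranking metric**: `p` (ascending p-value; the denominator is shared
  within an order so raw and adjusted p rank identically) or `or`
  (descending OR).  Optimal-OR profiles across orders can be built under
  either metric; results with exposed-case or exposed-control counts
  below 100 are flagged as fragile.
- **Protective combinations** (OR < 1) are ranked together with risk
  combinations through the two-sided Wald statistic.

Subjects with unknown smoking status stay in "total"-group analyses but
are excluded from every smoking-defined stratum; "ever" pools former and
current smokers.

## Resampling diagnostics

**Bootstrap rank stability.**  Cases and controls of the stratum are
resampled separately, with replacement, at their original sizes —
preserving the case-control balance the OR conditions on — and each of
the B replicates is rescanned with identical settings.  The report counts
how often each original top-10 combination reappears among the replicate
top-10/20/50.  Replicate tables that become degenerate are excluded from
that replicate's ranking (consistent with the main scan) and tallied.
An `identity` mode (every replicate is the original sample) exercises the
counting path deterministically.

**Permutation calibration.**  For each combination, case-control labels
are permuted among the subjects with defined exposure, holding exposure
fixed; the Wald statistic of each permuted table is computed exactly as
in the observed scan.  The permutation p-value uses the add-one estimator
(r+1)/(P+1), which cannot be zero at finite P.  The permuted mean and
variance are compared with the χ²(1) reference values 1 and 2: agreement
certifies the parametric p-values, and the approximation visibly degrades
for sparse high-order conjunctions, where the permutation p is the one to
trust.  P defaults to 100,000 at the command line; the test suite uses
10,000 (calibration moments converge at ~1/√P, so 10,000 resolves the
0.05/0.3 tolerances comfortably).

## Logistic models

Adjusted ORs come from maximum-likelihood logistic regression
(`statsmodels`, Newton iterations, |Δ parameters| tolerance 1e-8, 100
iterations): the exponentiated exposure coefficient of
status ~ exposure + age + gender + smoking + site, with categorical
covariates reference-coded against the first observed level and age
continuous in years.  With no covariates the estimate equals the crude
2×2 OR (saturated-model identity, asserted to 1e-6).  Separation and
non-convergence are flagged on the fit object, never silently returned;
no penalised fallback is attempted.

Stratum heterogeneity is tested with
status ~ exposure + stratum + exposure×stratum on the union of two
disjoint strata (default non vs ever smokers) and the Wald p-value of the
interaction coefficient.  In this covariate-free model exp(β_int) equals
the ratio of the two stratum ORs exactly; an adjusted variant accepts
extra covariates.  Type-I calibration of the test at α = 0.05 is verified
by simulation.

## Attributable-risk algebra

Levin's PAR f(RR−1)/(1+f(RR−1)) is paired with exposure prevalence among
*all controls* and crude ORs; the case-based (Miettinen) form
p_c(RR−1)/RR is the default whenever adjusted RRs are used, with the
multi-level genotype extension Σ p_c,i(RR_i−1)/RR_i as an alternative.
Combined PARs of independent factors multiply complements.  The inverse
RR = 1 + PAR/(f(1−PAR)) is exact (round-trip identity asserted to
1e-12); its infimum over f ∈ (0,1] is attained at f = 1.

## Synthetic cohorts

The generator draws population genotypes under Hardy–Weinberg equilibrium
at configurable allele frequencies, assigns smoking stratum, site and
gender categorically, samples disease status from a logistic model whose
linear predictor adds ln(OR) for every planted conjunction active in the
subject's stratum, and fills per-stratum case/control quotas by
oversampling — mirroring retrospective ascertainment.  Planting effects
on the logistic scale makes the *conditional* OR exact and
collapsibility-exempt here: with a single planted exposure and no other
status covariates the crude 2×2 OR targets the planted value directly,
which is what the recovery tests assert.  An optional site confounder
shifts both allele frequencies and baseline odds at one site, biasing the
crude OR while the site-adjusted OR recovers the planted value.

Default parameters are chosen to resemble the reference setting: stratum
sizes in the shipped `table9` scenario reproduce the study's
smoking-by-status margins exactly (321/752, 742/656, 431/315, plus
101/37 unknown); control genotype frequencies imply risk-genotype
prevalences near the reported non-smoking-control values (rs1014971
homozygote ≈ 40%, rs9642880 carrier ≈ 71%, rs710521 carrier ≈ 93%,
GSTM1 null 50%); ages are normal (controls 64 ± 10, cases 67 ± 10 years)
and the cohort is 75% male, as typical for bladder-cancer series.  The
baseline log-odds of −1 keeps both statuses common so quota filling is
fast; it is a nuisance parameter under case-control sampling.

What the generator does *not* emulate: linkage disequilibrium between
the markers (the panel is treated as independent loci), population
stratification, genotyping error, and dose-response smoking effects
within a stratum.  Passing tests therefore certify the statistical
machinery — enumeration, scoring, ranking, resampling, model fits, PAR
algebra — under the design assumptions, not robustness of scientific
conclusions to those real-data complications.

## Problem sizes in the test suite

The suite favours the smallest sizes at which each property is
informative: permutation calibration at 1,000 subjects with P = 10,000;
planted-effect recovery over 100 replicates of 2,000 + 2,000 subjects;
familywise-error control over 500 null replicates of 500 + 500;
interaction-test calibration over 400 replicates of 600 + 600.  Monte
Carlo tolerances are set from binomial/moment standard errors at those
sizes (e.g. CI-coverage bands of ±3 SE).  Where an assertion concerns an
expected rate (CI coverage under the null across 288 overlapping
candidates), it is averaged over replicates rather than asserted on a
single cohort, whose coverage fraction is highly variable because the
candidates share indicators.

## Known limitations

- Bonferroni is the only multiplicity correction (per order and stratum);
  no FDR variants.
- No bootstrap CIs for ORs — the bootstrap reports rank stability only.
- No VCF/PLINK input, imputation, phasing, or genome-scale panels; the
  exhaustive enumeration is intended for ≤ 7 polymorphisms.
- PARs are point values; no interval estimates.
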