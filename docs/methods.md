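# Methods

This note records the statistical model, the algorithms and the design
choices behind `popcompare`, including the points where the standard
literature leaves the arithmetic open and a choice had to be made.

## Data model

A population is a multiset of **individual histories**, each spanning one
projection interval: initial stage, fate (a destination stage or death) and
an integer vector of recruits per recruit stage. Two metadata axes travel
with every population and constrain all inference:

- **Sampling design.** Under `random` sampling the per-stage counts estimate
  the population's stage structure; under `fixed_per_stage` they were set by
  the experimenter. All resampling honours the design: the bootstrap and
  the permutation null are stratified by initial stage under fixed designs
  (an `--unstratified` escape hatch exists, since unstratified permutation
  would destroy experimentally fixed stage counts). The distance to the
  stable stage structure is only computed under random sampling — under a
  fixed design the observed stage distribution is a design artefact.
- **Reproduction data type.** `identified`/`anon3`: recruits credited to
  known parents with known fates. `anon2`: parents known, fates not — the
  arithmetic is identical here because fecundity is always credited to the
  parent's *initial*-stage column (see below), but the postbreeding
  dead-parent consistency check cannot be applied. `anon1` (anonymous
  reproduction): only population-level recruit totals per recruit stage are
  known; fecundity divides each total by the number of individuals in the
  declared reproductive stages, and resampling re-credits totals to groups
  in proportion to their share of reproductive individuals.

### Census conventions

The columns of **F** (like those of **U**) index the stage at the *start* of
the interval, so that **A = F + U** projects the start-of-interval stage
vector. What the census type changes is the biology behind the numbers, not
the credited column:

- *prebreeding*: reproduction happens right after the census; recruits must
  survive to the next census to be counted, and a parent may die after
  breeding — dead parents can legitimately carry recruits.
- *postbreeding*: individuals survive the whole interval and then reproduce
  with the fertility of the stage they arrive in; a dead parent with
  recruits is inconsistent data and is rejected (where parent fates are
  known).

The synthetic generator mirrors this: under prebreeding every individual
draws recruits from its initial stage's distribution; under postbreeding
only survivors draw, from their destination stage's distribution.

## Derived parameters

λ is the dominant eigenvalue of **A** (eigenvalue of maximal real part among
the numerically real ones; for a nonnegative matrix this is the Perron
root). The stable stage structure and reproductive value are the right and
left dominant eigenvectors, rescaled nonnegative and normalised to sum
to 1. R₀ is the dominant eigenvalue of **R = FN** with **N** = (I − U)⁻¹
the fundamental matrix; generation time T = ln R₀ / ln λ. Sensitivities
are s*ᵢⱼ* = v*ᵢ*w*ⱼ*/⟨v, w⟩ and elasticities e*ᵢⱼ* = (a*ᵢⱼ*/λ)s*ᵢⱼ*
(summing to 1).

Degenerate cases are data, not crashes: T is reported *absent with a
reason* at λ = 1 (replacement) or R₀ ≤ 0; an estimated stage with survival
1 (spectral radius of U at 1) makes R₀/T undefined for that fit; a diagonal
matrix with tied eigenvalues returns the uniform structure with a warning.
Resampling replicates where a parameter is undefined are skipped and
counted; results with more than 10% skipped replicates are flagged
unreliable.

## Resampling engine

Bootstrap and permutation replicates differ from the original data only in
the multiplicity of each *distinct* history, so all replicated computation
runs on integer count vectors over the shared basis of distinct histories
(canonically ordered: initial stage, destination — death last — then the
recruit vector lexicographically, so every run and platform enumerates
identically):

- bootstrap = multinomial draw over history frequencies (per initial-stage
  stratum under fixed designs);
- permutation = shuffling the pooled history codes and cutting the row into
  group blocks (within strata when stratified);
- blocks of replicates become stacked (U, F) matrices by one matrix
  multiplication, and λ/R₀/eigenvectors come from batched LAPACK solves.

This is mathematically identical to resampling individuals one at a time
and is what makes the 500×999-replicate simulation studies below run in
seconds. Individual-level `bootstrap_sample` and `permutation_split` are
also exposed and tested for distributional agreement with the counts-level
path. Seeding: every analysis spawns child streams from a master
`SeedSequence`, so a given seed reproduces results bit-for-bit, and the
statistics' symmetry is made literal by processing groups in a canonical
order regardless of how the user listed populations.

## Tests, intervals, power

**p-value convention.** p = (number of replicates strictly greater than the
observed statistic)/n_reps, with no add-one correction. The add-one
variant `(b+1)/(B+1)` is deliberate future work; the strictly-greater form
is what the rest of the package (critical values, power) is consistent
with. Only two-tailed tests exist, implemented as upper-tail tests on
nonnegative distance statistics, which fold both tails. No multiplicity
correction is applied; reports print the number of tests performed.

**Intervals.** Percentile method: endpoints are the α/2 and 1−α/2 empirical
quantiles of the replicate vector with linear interpolation between order
statistics (numpy's default rule), plus the simulated median. BCa is noted
as a possible refinement and not implemented.

**Power.** Critical value = empirical (1−α) quantile of the permutation
null (`method="higher"`, i.e. the smallest null value with at least 1−α of
the mass at or below it); ties at the critical value count as
non-rejection. The alternative distribution bootstraps each population
independently. *Known property:* because the alternative is centred on the
observed parameter values, the estimate carries the between-sample noise
twice under a true null; its expectation there is ≈ 0.17 for the pairwise
λ test (normal theory: P(|N(0, 4σ²)| > 1.96·√2σ) ≈ 0.166), not α. The
acceptance suite documents this with a dedicated (failing) calibration
check; the type-I error of the *test itself* is calibrated (≈ 5%).

**SSS-distance test.** The observed statistic is the Keyfitz Δ between the
observed stage proportions and the stable structure of the fitted matrix.
The null must represent a population truly at its stable structure, so the
replicates are bootstrapped *under the hypothesis*: stage counts are drawn
Multinomial(n, SSS of the fitted matrix) and fates/reproduction are
resampled within stages from the observed histories; each replicate's Δ
compares its own stage proportions with its own refitted stable structure.
A naive full bootstrap is not calibrated (it stacks resampling noise on the
observed deviation, pushing p towards 1); the chosen construction gives
approximately uniform p-values over populations simulated at their own SSS
(Kolmogorov–Smirnov check in the test suite).

**Planned comparisons.** Groups pool by concatenating individuals —
parameters are re-extracted from the pooled collection, never averaged.
Groups within a contrast must be disjoint; contrast sets that reuse a
population are allowed and flagged nonorthogonal.

## LTRE

Fixed one-way design: reference Ā is the elementwise mean matrix (or a
designated control population); contributions for population *m* are
c*ᵢⱼ* = (a*ᵢⱼ*⁽ᵐ⁾ − āᵢⱼ)·s*ᵢⱼ* with sensitivities evaluated at the midpoint
matrix ½(A⁽ᵐ⁾ + Ā) — the midpoint (rather than mean-matrix) evaluation was
chosen because it halves the leading error term of the first-order
expansion; the per-population residual λ⁽ᵐ⁾ − λ(Ā) − Σc is reported.
Random design: V(λ) ≈ Σ cov(aᵢⱼ, aₖₗ)·sᵢⱼ·sₖₗ with covariances across
populations (denominator n−1) and sensitivities at the mean matrix;
requires ≥ 3 populations.

## Sample-size scaling

The scaling analysis asks what would happen had 1.2ᵏ times as many
individuals been sampled *with identical vital rates*: each distinct
history's count is multiplied by the factor and integerised by
largest-remainder rounding (total = round(1.2ᵏ·n), every proportion moved
by less than 1/n). Step k reruns the randomization test, the power
estimate and the tracked confidence interval with its own derived seed.
This is an idealisation — a real larger sample would show a different
composition by chance — and the integerisation makes the per-step power
sequence slightly jagged (jumps of up to a few percent from O(1/n)
composition shifts, beyond pure Monte-Carlo noise), though the trend and
the ~n^(−1/2) shrinkage of CI widths are robust.

## Synthetic data

The generator draws each individual's fate from its stage's multinomial
fate distribution and recruit counts from Poisson (default) or fixed-count
distributions around declared means — it emulates the *data classes* of
field studies (census type, sampling design, reproduction types by erasing
parentage), not any particular species. It does not model density
dependence, environmental stochasticity, overdispersed reproduction or
multi-year histories; simulation results below therefore speak to sampling
noise under the stated designs, not to those complications.

## Simulation-study sizes

The test suite's simulation studies use: a two-stage juvenile/adult design
(juvenile: stay 0.3 / promote 0.4 / die 0.3; adult: survive 0.7; adult
fecundity 1.2 Poisson recruits, prebreeding, random sampling); 500 dataset
pairs of 50 individuals per group at 999 permutations for type-I error
calibration; 500 datasets of 200 individuals at 999 replicates for 95% CI
coverage (observed coverage ≈ 94–95%); 6 inflation steps at 10,000
replicates for the scaling pattern; exhaustive enumeration up to 10 pooled
individuals as the permutation oracle. All studies are seeded and
deterministic.

## Known limitations

- anon1/anon2 resampling semantics are one defensible reconstruction of
  anonymous-reproduction bookkeeping; alternatives exist (e.g. treating
  recruit totals as random rather than fixed under the bootstrap).
- The power estimator's upward bias under near-null effects (above) is a
  property of the estimated-alternative construction itself.
- Percentile CIs undercover slightly for strongly skewed parameters (R₀ at
  small n); BCa would improve this.
- Histories span one projection interval; longitudinal multi-year data and
  parentage inference are out of scope.
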