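# Methods

This note documents the models implemented in `contingency_lab`, the
defaults and numerical choices, what the synthetic-data generators do and
do not emulate, and the package's own design decisions where the
underlying procedure left genuine freedom.

## Wright–Fisher focal-allele simulation

A haploid asexual population of fixed size *N* evolves in discrete
generations. Per generation, in order:

1. **Background mutation.** Each individual acquires Poisson(*U*)
   mutations (default *U* = 7 × 10⁻⁴ per genome per generation, a mean of
   published genomic estimates for this system). Each mutation occurs at a
   new site and draws its selection coefficient from a discrete
   distribution of fitness effects (DFE) given as (effect, proportion)
   classes. Fitness is multiplicative across carried mutations.
2. **Focal mutation.** Focal-wild-type individuals mutate to the focal
   allele with probability μ (default 1.72 × 10⁻⁷, the fluctuation-test
   estimate for `lacI⁻` in the ancestor). The focal allele multiplies
   fitness by 1 + *s* (default *s* = 0.0831, its measured benefit in
   lactose) and never back-mutates.
3. **Resampling.** The next generation is drawn multinomially with
   probabilities proportional to count × fitness; population size is
   exactly *N* every generation.

A replicate stops when the focal frequency exceeds the fixation threshold
(default 0.95) or at the horizon (default 8,000 generations).

**Representation.** The population is stored as counts per
(fitness, focal-state) class, with equal classes merged. Selection and
resampling depend on genotype only through these two quantities, so the
class representation is distributionally exact while keeping *N* = 10⁵
over thousands of generations tractable. Mutation events are drawn in
aggregate (Poisson(*N U*) events assigned to classes proportional to
counts); the probability that one individual mutates twice in a single
generation is O(*U*²) and is ignored.

**DFE default.** The six-class default (deleterious −0.10/−0.03/−0.01 at
30% each; beneficial +0.01/+0.03/+0.08 at 5/3/2%) is a documented,
configurable placeholder preserving the three-deleterious +
three-beneficial structure of the study it mirrors; the study's own class
values live in supplementary material that prints no numbers in the main
text. Because the placeholder allots 10% of mutations to beneficial
classes, clonal interference is strong, and simulated substitution
frequencies at large *N* (≈80% in constant lactose, ≈69% combined at
*N* = 10⁵) sit below the headline value reported with the original DFE
(91.5%). Comparisons against that printed value should re-run the sweep
with the original class table via `SimConfig(dfe=...)`.

**Fluctuating regimes.** Regimes alternating glucose and lactose every
2,000 generations are not simulated directly. The same replicates are
censused at generation 2,000; focal mutations unfixed by then are assumed
lost in the glucose epoch, and the second lactose epoch contributes an
independent chance, giving *f*ₛ = *f*₂ₖ + *f*₂ₖ(1 − *f*₂ₖ). The
three-regime combined value is the unweighted mean of the constant-lactose
value and two copies of the extrapolation (each regime contributed equally
many experimental populations; the combination rule is this package's
choice, as no rule is printed). Daily-alternating environments are out of
scope — they would require correlated effects across sugars.

**Uncertainty.** *f*ₛ CIs are 2.5/97.5 percentiles of 1,000 bootstrap
resamples of the replicate fixation indicators.

## Fluctuation-test estimation

Mutant counts from parallel cultures follow the Luria–Delbrück
distribution, computed by the Ma–Sandri–Sarkar recursion
p₀ = e^(−m), pₙ = (m/n) Σᵢ pᵢ/(n−i+1) — equivalently a compound Poisson
with clone-size law P(j) = 1/(j(j+1)). The expected events per culture m
is estimated by maximum likelihood; the rate is m divided by total
culture cells (plated cells / plated volume fraction).

Numerical choices: the likelihood is maximized over log m (bounded,
tolerance 10⁻⁶); counts at or above a censoring cap (default 1024) enter
as the tail mass P(count ≥ cap), bounding the O(n²) recursion without
discarding jackpot information; partial plating is handled by binomial
thinning of the distribution (thinning matrix precomputed per assay);
all-zero assays return a boundary estimate (rate 0) with only an upper
bound. 95% CIs come from the profile likelihood at a 1.92
log-likelihood-unit drop. Plating-efficiency correction multiplies counts
by 1/p_eff (rounding ties-to-even on a 10⁻⁹-snapped quotient) *before*
estimation, mirroring the laboratory pipeline this reproduces; folding
efficiency into the likelihood instead is available via the thinning
machinery but is not the default.

## Competition fitness

Absolute (Malthusian) fitness over d serial-transfer days with 100-fold
daily dilution is w = ln(100^d · N(f)/N(i)); only within-competitor count
ratios matter, so raw colony counts and common-volume densities are
interchangeable (the caller fixes the convention). Relative fitness is the
ratio of Malthusian parameters and s its excess over 1. Replicate batches
get t-based 95% CIs (the interval form is this package's choice);
replicates with an extinct competitor are excluded with a warning, and a
reference competitor with zero net growth (|w_b| < 10⁻¹²) is rejected as
an undefined ratio.

## Baranyi–Roberts growth and virtual competitions

The single-strain model is d*N*/d*t* = r α(t) N (1 − (N/k)^ν) with
α(t) = q₀/(q₀ + e^(−vt)) and N(0) = y₀. Because α only rescales time, the
trajectory has the closed Richards form in adjusted time
A(t) = t + ln((e^(−vt) + q₀)/(1 + q₀))/v, which the package evaluates
directly; an independent ODE integration agrees to ~10⁻¹⁰ OD and the
closed form is what makes least-squares fitting fast. Lag is defined
analytically as λ = ln(1 + 1/q₀)/v (evaluated as softplus(−ln q₀)/v so the
nearly-equivalent small-q₀/large-v ridge of the likelihood surface cannot
overflow); a geometric tangent-construction lag is reported alongside.

Fitting minimizes squared OD residuals over all six parameters on a log
scale (positivity without hard bounds) from a fixed, versioned multi-start
grid over (q₀, v); the growth-rate seed is the log-OD slope over the
mid-growth window (0.1–0.6 of the maximum), excluding noise-dominated
near-zero readings. Flat curves (range < 2% of maximum) and fits that do
not at least double the initial density are returned as flagged failures,
never exceptions. On noiseless synthetic curves all parameters are
recovered to well under 1%; under 0.005-OD noise a 1.13 h lag contrast
between strain groups (5.00 vs 3.87 h, 50 replicate curves each) is
recovered within 0.2 h.

Virtual competitions couple two strains through the summed density —
dNᵢ/dt = rᵢ αᵢ(t) Nᵢ (1 − ((N_a + N_b)/kᵢ)^νᵢ), growth-only (negative
rates clamped to zero once a strain's pool is exhausted) — integrated with
LSODA at rtol 10⁻⁸. Virtual relative fitness uses the same
Malthusian-ratio form as plate competitions,
w = ln(N_a(T)/N_a(0)) / ln(N_b(T)/N_b(0)), so direct and virtual estimates
are commensurable; the ratio (rather than difference) form and the
defaults init_ratio = 0.5, horizon = 24 h are this package's choices.
Identical competitors give exactly 1.0; a zero-net-growth competitor
flags the result as undefined.

## Mutation-set similarity

Sørensen–Dice similarity 2|A∩B|/(|A|+|B|) between clones' mutated-locus
sets; loci are matched by identifier, so gene-level labels give gene
granularity (two different substitutions in one gene count as shared) and
position labels give site granularity. Two empty sets are undefined and
flagged rather than scored. Group structure is summarized by mean pairwise
similarity within each group and between groups; the null reassigns clones
to labels uniformly with group sizes preserved, and each statistic's
p-value is two-sided by absolute deviation from the permutation mean with
the add-one correction (1 + hits)/(1 + n_perm). Ties at zero deviation
make the constant-statistic case return exactly p = 1.

## Exact statistics

Wilson score intervals (the interval form that reproduces the printed
12/24 bounds, verified against the score-equation roots); exact binomial
tests with the point-probability two-sided convention; Fisher's exact test
by enumeration over the hypergeometric support with integer numerators, so
tie comparisons in the two-sided sum are exact and tail sums agree with
independent enumeration to 10⁻¹². Degenerate tables (an empty row or
column) return p = 1 with a warning. p-values are returned at full
precision; rounding is left to presentation.

## Synthetic data: what it does and does not emulate

The generators produce data with exactly the statistical structure the
estimators assume: additive truncated-Gaussian OD noise (default sd a free
fixture parameter, 0.005 OD in the recovery experiments — no magnitude is
published for the plate reader); Luria–Delbrück counts via binomial
mutation seeding at each doubling of an expanding culture with
deterministic doubling of mutant clones (clone sizes are powers of two, a
discretization that leaves the zero-class probability e^(−m) exact and the
MSS estimator's median recovery within 10% at m ≈ 5); competition counts
sampled multinomially (or Poisson) around frequencies that invert the
fitness estimator, rescaled to a common plated volume; and mutation
profiles built from group-level marker vectors (inclusion probability
p_within where a group's marker is set, p_shared otherwise), which makes
expected within-group overlap exceed between-group overlap by Jensen's
inequality whenever p_within ≠ p_shared and collapses to an exchangeable
i.i.d. null when they are equal.

Passing recovery tests on these inputs therefore demonstrates estimator
correctness under the assumed models — not robustness to features real
data have and the generators lack: OD drift and autocorrelated reader
noise, diauxie in two-sugar media, mutant/wild-type growth-rate
differences and post-plating mutations in fluctuation assays, marker
costs and frequency dependence in competitions, or phylogenetic
correlation among sequenced clones.

## Problem sizes

The shipped test suite and acceptance script run the simulation sweep at
N = 10³ and 10⁴ with 50 replicates and N = 10⁵ with 20 replicates (the
replicate count the mirrored study used at that size), 500 fluctuation
assays of 10 cultures for rate recovery, 50 noisy growth curves per strain
group, 200 synthetic competitions, and 500 permutation datasets for null
uniformity — sizes chosen so the complete analysis reruns from scratch in
a few minutes on one core while keeping Monte-Carlo error well inside
each assertion's tolerance.

## Known limitations

- The Wright–Fisher engine models no linkage maps, recombination,
  diploidy, or environment switching within a replicate; glucose epochs
  enter only through the loss assumption in the extrapolation formula.
- The fluctuation model assumes equal mutant and wild-type growth and
  complete plating of survivors after thinning; differential mutant
  fitness is out of scope.
- Virtual competitions stay in OD units (no OD-to-CFU calibration) and do
  not model diauxic two-sugar dynamics.
- The similarity module compares pre-called mutation profiles; it performs
  no variant calling or annotation.
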