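# Methods

`admixdemo` reconstructs the demographic history of three-way admixed
American populations (Mexican-American, Colombian, Puerto Rican panels with
Native American, European and African ancestry) from four complementary
signals: the length distribution of local-ancestry tracts, the amount of
identity-by-descent (IBD) sharing, the joint site-frequency spectrum (SFS)
of negatively ascertained Native-background variants, and
local-ancestry-conditioned allele frequencies.  Every stage is exercised on
synthetic data produced by the package's own generators, so this note
states both the models and what the generators do and do not emulate.

## Ancestry-tract model

An admixed population is described by a migration history `m[t, p]`: the
fraction of the population replaced `t` generations before present by
migrants from source `p ∈ {NAT, EUR, AFR}`.  The founding generation `T0`
has `Σ_p m[T0, p] = 1`, and no migration is allowed at generations 0–1 (a
generation-1 migrant would reach the present sample unrecombined).

Along a present-day haplotype, the ancestry process is approximated by a
Markov jump process whose states are `(entry generation t, source p)`.  A
lineage that entered `t` generations ago has passed through `t − 1`
meioses, so crossover breakpoints arrive at rate `t − 1` per Morgan; the
crossover at meiosis level `g` swaps to a haplotype standing at generation
`g + 1`, whose entry state follows the standing-population distribution
`E_{g+1}(t', p') = m[t', p'] Π_{v=g+1}^{t'−1}(1 − M[v])`.  The stationary
distribution of this chain is the present-day entry distribution `E_1`
(checked numerically in the tests).  Grouping states by source label makes
per-ancestry tract lengths phase-type distributed; expected per-bin counts
on finite chromosomes follow in closed form via the eigendecomposition of
the within-ancestry sub-generator, with three edge corrections (tracts
censored at one chromosome end, at both, and whole-chromosome tracts).
Conservation (`Σ_bins count × length = ancestry proportion × genome
length`) holds to better than 1% with fine bins.

Non-integer pulse times are discretized onto integer generations:
a founding at non-integer `t` becomes a founding at `⌈t⌉` followed by a
replacement of weight `⌈t⌉ − t` at `⌊t⌋` (so 13.02 generations → founding
at 14, 0.98 replacement at 13), which preserves ancestry fractions exactly;
partial pulses are mass-split linearly between the neighbouring
generations.

Fitting maximizes a Poisson likelihood of per-bin tract counts (30
log-spaced bins from the 0.2 cM local-ancestry detection limit to the
longest chromosome; bins with zero expectation and a positive observation
are impossible under the model).  Four model families are implemented:
simultaneous three-source founding; founding plus continuing European and
Native inflow (the MXL family); founding plus a second European/African
period (PUR); founding plus a second Native pulse (CLM).  Optimization is
bounded Powell from 10 random starts (cheap exploration, then one polished
restart from the best); infeasible parameter vectors are projected back
into the feasible region with a smooth penalty, because flat penalty
plateaus stall direction-set methods.  Model selection uses BIC by default;
bootstrap confidence intervals resample diploid individuals.

The forward generator paints chromosomes through the same migration
history by recursive lineage splitting: a haplotype standing `t`
generations ago is a fresh migrant with probability `M[t]` (forced at the
founding) and otherwise a crossover mosaic (Poisson, 1/Morgan, no
interference) of two independent haplotypes standing at `t + 1`; only
intervals ancestral to the sampled haplotype are propagated.  Because each
recursion branch draws fresh parents, the generator realises the
infinite-population limit; the finite-sample pedigree correlations of real
panels are not emulated, which is one reason refitted onsets scatter
slightly around the truth.  The default genome is 22 chromosomes with
real-autosome length proportions rescaled to 35 Morgans; recombination is
uniform per chromosome (map heterogeneity is not modelled).

Study defaults: MXL, onset 15.1 ga, founding NAT/EUR/AFR = 0.55/0.40/0.05,
continuing EUR and NAT inflow 0.02 per generation, 68 diploids; CLM, onset
13.02 ga, founding 0.25/0.67/0.08, second NAT pulse 4.8 ga of magnitude
0.05, 66 diploids; PUR, onset 16 ga, founding 0.20/0.65/0.15, second
EUR/AFR pulse 6.8 ga (0.15/0.05), 64 diploids.  The onsets, the CLM pulse
time, and the panel sizes are the reference values; the fractions and
magnitudes are this package's documented choices, set once from the populations'
ancestry proportions.  Calendar conversion uses 30 years per generation.

## IBD sharing and recent effective size

Between two haplotypes the time to the most recent common ancestor (TMRCA)
along the chromosome is piecewise constant with breakpoints at rate `2t`
per Morgan and stationary Exp(2Ne) redraws (a sequential Markovian
approximation).  A constant-TMRCA run with `t` below the length-implied
recency ceiling `τ = 100/u` generations is an IBD segment.  Runs with
TMRCA in `dt` begin at rate `2 t f(t) dt` per Morgan and have Exp(2t)
lengths, so segments of length ≥ u Morgans form a thinned Poisson process,
and their expected number per haplotype pair is

    E[N ≥ u] = Σ_chrom (L_c − u) · (1/Ne) · (1 − e^{−aτ}(1 + aτ)) / a²,
    a = 1/(2Ne) + 2u.

The estimator inverts this strictly decreasing function of Ne at the
observed mean segment count per pair; zero observed segments return
infinity.  The generator simulates exactly this thinned process (so the
estimator/simulator loop is exact up to Monte Carlo noise): at the
reference PUR configuration (Ne = 10,000, 55 diploids, ≥ 4 cM over 35
Morgans) about 3,000 segments are expected and the size is recovered to a
few percent.  Mutation, phasing error and IBD-detection error are not
modelled: the segments are true coalescent segments, which is the regime
the count formula describes.

Ancestry annotation of IBD segments intersects each segment with the two
haplotypes' local-ancestry tracts, reporting the cM-majority origin, the
label mismatch fraction and the number of internal ancestry switch points.
The switch-density trend (density of switch points per cM against segment
length) is a length-weighted least-squares slope with a two-sided
one-parameter bootstrap over individuals; each record is owned by its
first-listed individual so that a record is resampled exactly as often as
its owner (sharing it between both members would double-count it and
shrink the bootstrap variance — the null calibration test caught this).

## Negative ascertainment

To isolate variants on the Native background without trusting phased
ancestry at heterozygous sites, any site with a derived allele in an
outgroup panel, or whose only derived observations sit in segments without
Native ancestry, is discarded; remaining variants are attributed to the
Native background ("perfect ascertainment").  Per-site Native derived
counts are capped by each carrier's Native haplotype count, and the
variable per-site Native sample size is handled by hypergeometric
projection to a fixed target.  European-private variants that survive the
filter — overwhelmingly singletons — are quantified by running the same
filter on mock all-European pseudo-samples assembled from Eur/Eur
segments, and subtracted (truncating at zero).

The validation harness checks the claim that ascertainment acts like a
drastic bottleneck at the outgroup divergence: two sister populations
(split 12.1 kya) plus an outgroup (split 16.5 kya) are simulated forward;
all variants observed in 100 outgroup diploids are removed; and a
two-population model with a root crash (10-generation epoch of free size,
free recovered size, ancestral size fixed as the scale anchor, and the
mutation supply fixed at the simulation's known value — a bottleneck
drastic enough to erase pre-existing variation also erases the information
that would otherwise anchor the overall scale) is refit.  Desk-scale sizes
are 500 for the in-model populations and 5,000 for the outgroup
population, with 2M mutation opportunities; sampling is hypergeometric.
At these conditions the inferred bottleneck lands within about 10% of the
outgroup split, with in-split time and sizes within a few percent.  The
equivalence is intrinsically approximate: rare ancestral variants missed
by the finite outgroup panel (or lost along the outgroup branch) survive
ascertainment, look like old shared variation, and push the fitted
bottleneck earlier.  The leak grows with the ancestral rare-variant supply
relative to the panel, so configurations far from the
perfect-ascertainment regime recover the bottleneck time with a larger
(upward) bias — a real property of sample-based negative ascertainment,
not an artifact.

## Joint-SFS demography

The three Native ancestries are modelled by a split tree: ancestral size
`N_anc` until the founding bottleneck at `T_found` (size `N_bot` until
`T_recovery`, then recovered at `r · N_bot`, with `r` fixed at 100 — the
likelihood is insensitive beyond that value), one population splitting at
`T1` and the remaining pair at `T2 ≤ T1`, each branch at its own constant
size; the intermediate ancestor of the later pair stays at the recovered
size.  Because the model has no migration between Native branches, the
marginal dynamics of a pair are unaffected by the third population's
split, and inference uses the composite likelihood of the three pairwise
two-population spectra.

Expected spectra come from a deterministic frequency-grid engine: masses
on a uniform grid evolve under the tridiagonal Wright-Fisher diffusion
generator `(1/4N) Δ²(x(1−x)φ)`, advanced with matrix exponentials (exact
in epoch duration); splits copy the one-population vector onto the
diagonal of a two-population array, whose axes then drift independently
(25-generation slices with trapezoidal corner injection of new
mutations).  The injection rate `G·μL` per generation reproduces the
neutral `θ/i` spectrum exactly at stationarity on the grid nodes.  Sample
spectra are binomial-sampled from the grid and refined by quadratic
Richardson extrapolation over three grid sizes (default `n+10, n+25,
n+40`); extrapolation is essential because a finite grid cannot represent
sub-grid frequencies and systematically under-predicts singletons (error
≈ n/2G per grid).  Fits explore with the default grids and polish the
winning ordering on successively finer grid triples (up to 150/200/250).
The staged polish matters because the likelihood in a branch's size is
nearly flat once its drift is small — on a young branch the rare-variant
load is almost independent of N (mutation supply scales with N,
per-mutation sample visibility with 1/N), so the size is informed only by
the few effectively coalescing lineages — and tiny grid residuals can
displace the optimum a long way along that valley.  Even so, the
maximum-likelihood size of a large young branch retains a sampling spread
of roughly ±15–20%, which is why the recovery study averages replicates
and quotes bootstrap intervals.  The engine is validated against the
forward per-locus simulator (per-entry chi-square ≈ 1) and against
msprime's expected branch-length SFS for a clean split model.

θ enters linearly and is profiled analytically (`θ̂ = Σobs/Σexp` over
unmasked entries); only the absent and fully fixed corners are masked.
With θ profiled the spectra constrain sizes and times only relative to
the ancestral size, so fits fix `N_anc` numerically and
`calibrate_physical` anchors the founding epoch (default 16,000 years at
30 years/generation), scaling all times and sizes linearly and returning
the implied mutation rate `μ = θ/(4 N_ref L)`; users can re-anchor without
refitting.  Under this anchor the recovered branch sizes are invariant to
the scale ridge left by a drastic founding bottleneck.

The forward simulator propagates per-locus allele frequencies by binomial
resampling generation-by-generation (active-locus bookkeeping keeps the
cost proportional to the lifetime of segregating variants).  Mutation
origins are allocated across root standing variation (drawn from the
discrete `1/k` equilibrium) and single-origin mutations uniform in time,
weighted by `2N` per branch-generation (infinite sites); the simulator
reports the effective `μL` implied by treating the requested loci as the
full mutation supply, which fixes θ when refitting simulated data.

Study defaults for the recovery study: `N_anc` 10,000; founding 16 kya
with `N_bot` 30 (recovered 3,000) and recovery at 14 kya; splits at 12.4
and 11.9 kya (the reference splits are nearly simultaneous — orderings are
statistically indistinguishable, and all three appear among bootstrap
replicates); branch sizes MXL 64,000 and PUR 2,000 (the 32-fold reference ratio), CLM 15,000 (no established reference; set between the two);
simulation samples 60/30/16 haploids projected to the reference 40/20/10.
Post-contact bottlenecks are supported as fully fixed epochs on a terminal
branch; the sensitivity report refits with and without the crash from the
same start (so the comparison is protocol-symmetric) and reports the
pre-crash size inflation, which grows with severity.

## EM allele frequencies

With unphased genotypes, the two haplotypes of an individual are modelled
as independent Bernoulli draws from their own ancestry's frequency, making
the genotype likelihood phasing-free: `P(G=1 | a,b) = f_a(1−f_b) +
f_b(1−f_a)`, etc.  Per-site posteriors over a 201-point frequency grid
(0.5% resolution) combine the likelihood with per-ancestry priors; the
priors themselves are estimated self-consistently by iterating posterior
computation and prior-averaging for 20 iterations (the plain EM's
marginal likelihood is asserted non-decreasing on every run).  All
genotype classes except the ancestry-heterozygous heterozygote are
separable in the two frequencies, so batches of sites are processed with
cached `exp(n₁ L₁)` coupling kernels, one per heterozygote count; sites
involving three ancestries are contracted explicitly on the product grid.
Sites with any missing genotype or ancestry call are excluded, and only
non-monomorphic sites are reported.

Monomorphic (undetected) sites re-enter through a corrected
maximisation step: a site at frequency `f` on a background sampled with
`H` haplotypes on average escapes detection with probability about
`(1−f)^H`, so the `n₀` unobserved sites are distributed over the grid as
`prior(f)(1−f)^H` and averaged together with the polymorphic-site
posteriors.  This reconstruction is validated by a simulation oracle (the
corrected prior is closer in KL divergence to the generating frequency
distribution than the uncorrected one).

Intervals are highest-posterior-density sets on the grid, widened by half
a grid step on each side because each grid point represents a frequency
cell.  The validation panel mirrors the pseudo-admixture construction: 84
diploids whose haplotypes derive 50–50 from two source populations,
100,000 sites on a 50-Morgan chromosome, with per-population frequencies
from a Balding-Nichols model (Fst 0.15) around a neutral `1/f` ancestral
spectrum truncated at 0.005.  On this panel fewer than 0.5% of polymorphic
sites per ancestry have a true sample frequency outside the 95% interval
(the intervals target population frequencies, so they cover sample
frequencies conservatively), and estimates are exactly invariant to
injected phase-switch errors.  The cross-population differentiation test
bootstraps individuals within each panel and reports a two-sided
bootstrap p (null-uniform by construction) with Bonferroni adjustment.

## Numerical choices and limitations

- Optimizers are bounded Powell (derivative-free; the tract likelihood is
  only piecewise-smooth in pulse times because of integer discretization).
  Infeasibilities are repaired smoothly rather than penalised with flat
  plateaus.  All fits are deterministic given the seed.
- Expected-count floors (1e−12) prevent roundoff zeros from turning the
  Poisson likelihood to −∞ for ancestries genuinely present in a model.
- The problem sizes used by the tests and the acceptance study (20 seeds
  for tract refits, 10 for IBD, 3–4 for the ascertainment harness, 6–8M
  mutation opportunities for the SFS studies) are the package's desk-scale
  defaults; they keep every recovery within a few percent Monte Carlo
  noise of its target.
- Known limitations: uniform recombination maps; no genotype-likelihood
  (coverage) modelling; tract simulation in the infinite-population limit;
  IBD segments without detection error; the negative-ascertainment
  bottleneck equivalence degrades away from the perfect-ascertainment
  regime; the composite likelihood understates parameter uncertainty
  relative to a full joint likelihood (bootstrap CIs are therefore over
  blocks of loci).
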