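# Methods

This note documents the models behind `capturebias`: what the synthetic
generator emulates, how each estimator is defined, the numerical choices,
and the limits of what the tests demonstrate.

## The capture-simulation model

A simulated experiment is (genotype truth, library, assay, read budget).

**Genotypes.**  Balding–Nichols structure: per SNP an ancestral
alternative-allele frequency p0 ~ Uniform(0.05, 0.95); each population
with drift F > 0 draws its frequency from Beta(p0(1−F)/F, (1−p0)(1−F)/F)
(F = 0 keeps p0); individuals draw genotypes Binomial(2, p).  The Hudson
Fst between two populations with common F recovers F, which gives the f4
machinery a known null (exchangeable libraries from one population) and
known alternatives.

**Molecules.**  A library holds `complexity` distinct endogenous
molecules.  Each carries a target SNP (uniform over the panel), a center
offset uniform in ±200 bp, a fragment length (log-normal, median 55 bp,
log-SD 0.25 by default, floored at 30 bp — only fragments long enough to
map are modeled), and a GC fraction Beta-distributed around 0.41
(concentration 35, giving an SD ≈ 0.08 similar to real fragment GC
spreads).

**Capture weight.**  Each molecule's probability of being sequenced is
proportional to

    efficiency_s × logistic(slope·(L − midpoint)) × exp(−c·(gc − g*)²) × exp(−d/h)

where `efficiency_s` is a per-SNP log-normal with mean 1 and log-SD
`efficiency_spread`, d is the gap between the molecule and its target
(zero when it overlaps), h is `offtarget_halfwidth`, and (c, g\*) are the
GC curvature and optimum.  Two rounds of capture square the weight.  The
logistic/quadratic forms are modeling choices — real capture chemistry is
not published at this level of detail — so distance/length/GC behavior is
validated only against the simulator's own kernels, by independent
numerical integration in the tests.

The quadratic GC response needs a location parameter (`gc_optimum`) as
well as a curvature: an optimum below the genomic mean produces a
downward GC shift of enriched reads (Arbor-like), above it an upward
shift (1240k-like).

**Allelic bias.**  Per assay, each SNP draws a reference-read probability
β_s from a normal(bias_mean, bias_sd) truncated to [0.01, 0.99].  The
draw is keyed by (master seed, assay name) only, so every library
captured with the same assay shares the same β — the reagent owns the
bias.  This shared draw is precisely what creates positive f4 symmetry
statistics between libraries processed with the same reagent.  Bias from
mapping (common to all platforms) is folded into `bias_mean`; an optional
per-length-bin SD emulates the empirical pattern that longer, more
reliably aligned fragments show less bias.  Homozygous sites always yield
the homozygous allele: sequencing error and post-mortem damage are not
modeled (libraries are treated as damage-repaired), so `other_count` is
zero in simulation and β is the only source of allelic distortion.

**Reads and duplicates.**  Reads are drawn with replacement from the
weighted molecule pool; a Binomial(n_reads, 1 − endogenous_fraction)
share is non-endogenous background hitting no target.  Pre-dedup counts
tally reads; post-dedup counts tally distinct molecules.  Above a pool
cap of 10⁷ molecules the pool is not materialized and every read is
treated as a distinct molecule drawn i.i.d. from the weighted attribute
law; the neglected collision probability is below n_reads²/(2·complexity)
(≈ 5×10⁻⁶ per pair at complexity 10⁸ and 10³ reads), which also makes the
"post-dedup = pre-dedup in the infinite-complexity limit" property exact.

**Presets.**  Four profiles (`shotgun-like`, `twist-like`, `arbor-like`,
`1240k-like`) encode the qualitative platform contrasts: efficiency
spreads solve Φ((ln 0.1 + s²/2)/s) = q for low-coverage fractions q = 1%,
5%, 16%, 28%, bias SDs are 0.11, 0.12, 0.18, 0.15, and the GC/length
responses point in the platform-specific directions.  Because observed
coverage adds Poisson sampling noise on top of the efficiency spread,
simulated low-coverage fractions at finite depth sit a few points above
the pure log-normal tail; the ordering across platforms is the meaningful
output.  What the generator does *not* emulate: damage patterns, mapping
and alignment (reads are abstract records), probe tiling, linkage
disequilibrium within blocks, and real panel ascertainment — so passing
tests demonstrate estimator correctness under the model, not performance
on any particular real data set.

## Reference-bias EM

Sites enter when reads show both alleles.  Default `truncated` mode keeps
all reads and divides the binomial likelihood by 1 − p^n − (1−p)^n,
conditioning on the ascertainment; `decrement` mode discards one read of
each allele and uses a plain binomial on the remainder.  The residual
after decrementing is not exactly binomial, so truncated is the default;
the two agree on the mean within 0.01 at depth ≥ 15 in the tests and both
are exposed because the verbal "count the additional reads" protocol
matches the decrement reading.

The latent distribution lives on K = 100 interior midpoints (avoiding
p ∈ {0, 1}, where the truncated likelihood is undefined).  The weights'
log-likelihood is concave, so EM from the uniform start converges to the
global maximum; the brute-force simplex grid search in the tests confirms
the fixed point to 1e−4 on small instances.  Likelihood rows are
aggregated over unique (n, k) pairs, which makes the EM cost independent
of SNP count at fixed depth.  SNPs are weighted equally regardless of
depth — the estimand is the across-SNP distribution, not a read-weighted
average.  Defaults: max 2000 iterations, relative log-likelihood
tolerance 1e−9; non-convergence sets a flag rather than raising, and the
mean/SD are already stable well before the weight vector itself settles.
Monotonicity of the log-likelihood is asserted every iteration.

## f4 statistics and the block jackknife

Pseudohaploid calls pick one random allele-informative read per SNP
(post-dedup by default: one molecule, one vote); each (library, assay)
sample has its own stream derived from the master seed and its labels.  A
SNP enters an f4 only when all four samples are non-missing, which avoids
imbalance with pseudohaploid data.  Blocks are contiguous 5 Mb genomic
spans by default (a field-standard scale for LD robustness; equal-count
blocks are offered for unplaced panels).  The standard error uses the
weighted delete-one-block jackknife with Busing-style variance, which
reduces to the classic jackknife for equal blocks and matches
SD(terms)/√n on i.i.d. terms.  The scan reports one-sided Z because
technical bias predicts positive f4.  Tail probabilities are exact
normal tails: Z > 1.7 ⇔ p < 0.045; note that Z > 3.1 corresponds to
p ≈ 9.7×10⁻⁴, not 10⁻⁴ — a figure sometimes quoted — and this package
reports the exact value.

## The compatibility filter

Reference-match rates pool post-dedup reads across libraries per SNP and
platform, restricted to (library, SNP) pairs where the individual is
heterozygous (ground truth in synthetic mode; a ≥ 0.9 imputation
posterior is the intended real-data input, imputation itself being out of
scope).  SNPs with fewer than 10 pooled reads are omitted — with no depth
floor the empirical rate difference at a SNP is dominated by noise.  A
SNP passes when |rate_a − rate_b| < 0.04, strict inequality.  The
operating characteristics follow binomial tails: at pooled depth D the
rate-difference SD is √(2·0.25/D) ≈ 0.05 at D = 200, so a 0.10 offset is
detected ~89% of the time there and essentially always at D ≳ 2000, while
clean SNPs pass at a rate that grows with depth.  The filter is
deliberately unoptimized — a single threshold on a single contrast — and
its evaluation (mean pairwise Z before vs after) is the honest measure of
what it buys.

## Problem sizes and numerical choices

Simulated studies use 20,000-SNP panels over five 40 Mb chromosomes
(50 jackknife blocks), four analysis libraries plus ten rate-reference
libraries at mean depths 5 and 10, and 200 replicates for null
calibration — sizes chosen so every distributional claim has small Monte
Carlo error while a full run of the suite and the acceptance script
completes in minutes.  All randomness flows from one master seed through
CRC-labeled child streams (`_rng.child_rng`), so any component can be
re-run in isolation with identical draws.  Ties and degenerate inputs:
empty subsets raise `EmptyInputError` rather than returning NaN; ratio
statistics with zero denominators raise `UndefinedRatioError`; a jackknife
with identical leave-one-out estimates reports se = 0 and an undefined
(NaN) Z; thresholds in the near-target annotation are inclusive (≥) while
the bias filter is strict (<), each matching its defining rule.

## Known limitations

* The generator's capture-response forms (logistic length, Gaussian GC,
  exponential distance decay) are stylized; only their qualitative
  directions are meaningful.
* `simulate_read_counts` (the count-level shortcut used for replicated f4
  and filter studies) bypasses complexity and duplicates; conclusions
  about duplicate-sensitive quantities must use `simulate_capture`.
* The EM grid estimator returns a discrete distribution; its mean and SD
  are well identified, but the shape of the estimated weight vector is
  not (NPMLE-style solutions concentrate on few support points).
* Real-data inputs (imputation posteriors, quality filtering upstream of
  the count tables) are accepted but not produced by this package.
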