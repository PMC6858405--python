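# Methods

`bacrate` analyses variation in bacterial *accumulation rates* — substitutions
per site per year inferred from temporally sampled or dated isolates over
months to ~1500 years.  These rates sit between the mutation rate (per
generation) and the long-term substitution rate, and vary across species by
more than three orders of magnitude.  The package has three parts: a
population-genetic model of why accumulation-rate estimates decline with
sampling time; curation and diversity machinery for rate/trait compilations;
and a phylogenetic-comparative statistical pipeline.  A synthetic-data module
generates every input the pipeline consumes.

## Wright-Fisher transition-matrix model

A mutation with selection coefficient `s` (mutant fitness `1 - s`,
`0 <= s < 1`) enters a haploid population of `N` chromosomes as a single
copy.  Each generation its frequency `f` is first moved deterministically by
selection,

    f' = (1 - s) f / (1 - s f),

then resampled binomially (`N` draws with success probability `f'`).  The
state is the full probability vector over copy number `0..N`; the transition
matrix has `B(N, x, i, s)` in column `i`, and the columns at `0` and `N` are
absorbing because the selection map fixes both endpoints.  Retaining the
boundary classes in the state vector (rather than summing only over interior
copy numbers) is what keeps total probability conserved to machine precision
over thousands of generations, and it is required for the divergence
calculation because fixed mutations contribute `x/N = 1` permanently.

**Generation indexing.** The expected divergence of a sampled lineage from
its ancestor is

    D(N, s, t) = sum_{v=1..t} E[x/N at generation v],

where generation `v = 1` is the *initial* single-copy state (no transition
applied).  Two checks pin this convention down: neutrally the mean frequency
is a martingale, so `D(N, 0, t) = t/N` exactly; and for large `N` the drift
term is negligible and `D ~ (1/N) * sum_{v=1..t} (1-s)^(v-1)` (verified to
5% relative at `N = 1000, s = 0.1, t <= 100`).

The relative accumulation rate is `A(N, s, t) = D(N, s, t) / D(N, 0, t)`.
(The factor of two for two diverging clones cancels in the ratio.)  `A = 1`
neutrally, declines monotonically in `t`, `s` and mean selection strength,
and satisfies the diffusion scaling `A(N, s, t) = A(zN, s/z, zt)`:
equivalently, when selection is measured as `N*s` and time in units of `N`
generations, the curve is independent of `N` (numerically the gap is ~2e-3
between `N = 100` and `N = 200`).  Note the invariance does **not** hold with
`s` unscaled — in the deterministic limit `A ~ (1 - (1-s)^t)/(s t)` depends
on absolute generations — so all cross-`N` comparisons in the tests hold
`N*s` fixed.

**Distribution of fitness effects.** Selection coefficients are drawn from a
gamma distribution parameterised by `shape` and `mean_Ns` (mean of `N*s`), so
draws have mean `s = mean_Ns / N` with scale `mean_Ns / (shape * N)`.
Divergence is computed per draw and averaged across mutations (100 draws by
default) before dividing by the neutral expectation.  Draws with `s >= 1`
(impossible fitness) are capped at `1 - 1e-6`, i.e. treated as effectively
lethal; if more than half the draws are capped (e.g. `mean_Ns = 1000` with
`N = 100`) a warning is raised but the computation proceeds, since capped
draws are purged within a generation or two either way.  A single seeded
`numpy` generator per `DFESpec` makes curves reproducible.

**Problem sizes.** The default grids use `N = 100` over `0..4N` generations
and `N = 1000` over the first `0.1N`, both configurable; curve time points
are geometrically spaced and reported in units of `N`.  The Monte-Carlo
cross-check (`monte_carlo_divergence`) forward-simulates single-copy
trajectories under the identical selection-then-binomial scheme and is an
unbiased estimator of `D`; agreement within 3 standard errors at 20,000
replicates is part of the test suite.

## Curation of rate compilations

Rate tables carry one row per published-style estimate (species, rate,
sampling time in years, site class, hypermutator flag, study).  Three
exclusion rules are applied, each logged with its reason:

1. sampling time at most 1500 years (inclusive boundary);
2. estimates for all sites only (synonymous-only estimates dropped);
3. no hypermutator strains.

Surviving estimates are averaged per species.  The average is the
**arithmetic mean of raw rates** (a geometric option is provided); analyses
use `log10` of the mean rate.  Both choices are conventions — the averaging
scale is genuinely open, and the log base affects no correlation — and both
are isolated behind `average_by_species` / `log_transform`.

## piN/piS

Nucleotide diversity at non-synonymous vs synonymous sites is computed by
Nei-Gojobori (1986) proportion counting: each sense codon contributes the
fraction of its nine single-base changes that are synonymous as synonymous
site counts (changes to stops count as non-synonymous, giving e.g. TGG =
(3, 0) and TTT = (8/3, 1/3)); pairwise differences at multi-hit codons are
averaged over all orderings of the differing positions with equal weight;
per-pair piN and piS are diversities per site, averaged over all unordered
pairs.  Codon columns containing gaps, ambiguity codes or stops in either
sequence of a pair are skipped pairwise.  No multiple-hit (Jukes-Cantor)
correction is applied because within-species diversities here are small.
When piS = 0 the ratio is reported as undefined (None), never as 0.

## Phylogenetic comparative methods

**Independent contrasts** follow Felsenstein's pruning recursion: contrast
`(x_i - x_j)/sqrt(v_i + v_j)`, precision-weighted parent value, parent branch
lengthened by `v_i v_j/(v_i + v_j)`.  Polytomies are resolved arbitrarily
with zero-length branches (with a warning); a zero-length sibling pair is an
error unless the two values are equal (contrast 0).  The through-origin
regression of one trait's contrasts on another's equals the GLS slope under
Brownian covariance; the test suite asserts this to 1e-8, and contrasts are
additionally cross-checked against `ape::pic`.

Contrasts whose *expected standard deviation* — `sqrt` of the summed adjusted
branch lengths, the natural scale attached to a contrast — falls below a
threshold (default 0.21) can be filtered out before correlation, because
contrasts between near-identical taxa are dominated by measurement noise.
The threshold is a parameter, not a constant.

**Pagel's lambda** multiplies the off-diagonal entries of the Brownian
tip-covariance matrix by `lambda in [0, 1]`; the mean and rate are profiled
out of the multivariate-normal likelihood and `lambda` is maximised by
bounded Brent search (tolerance 1e-6), with the boundary candidates 0 and 1
always evaluated.  Significance is a likelihood-ratio test against
`lambda = 0` (chi-square, 1 df).  **Blomberg's K** is the observed
`MSE0/MSE` (mean squared deviation from the phylogenetic GLS mean, and its
GLS analogue) divided by its Brownian expectation
`(tr(C) - n / (1' C^-1 1)) / (n - 1)`; the permutation p-value shuffles trait
values across tips and counts permutations whose variance of standardized
contrasts is at most the observed one (999 permutations by default, seeded).
Both statistics are invariant to affine transformation of the trait and
match `phytools::phylosig` on fixtures.  **Sister pairs** for the paired
lifestyle comparison are the disjoint cherries whose two tips carry
different group labels.

## Classical statistics

Pearson correlations use the two-sided t-test p-value and pairwise-complete
observations.  The within-species sampling-time effect is a parallel-slopes
ANCOVA (`log10 rate ~ species intercepts + common slope * log10 time`),
fitted by OLS; groups with fewer than two estimates are dropped with a
warning.  The multiple regression z-scores response and predictors and
reports standardized coefficients with t-test p-values, raising on
rank-deficient designs and naming the collinear columns.  Group comparisons
use Welch's t-test (no equal-variance assumption) or a paired t-test;
identical paired samples return `t = 0, p = 1` rather than NaN.  All tests
are two-sided.

The smallest reliably detectable correlation uses the Fisher-z closed form
`atanh(r) = (z_{1-alpha/2} + z_{power}) / sqrt(n - 3)`; at `n = 34`,
`alpha = 0.05`, `power = 0.95` this gives `r = 0.570`, verified in the tests
by direct simulation of the rejection rate.  A one-sided test at the same
level would give 0.54; the default is two-sided for consistency with the
rest of the pipeline.

## Synthetic data

`simulate_tree` draws Yule pure-birth trees (explicit exponential waiting
times, one extra waiting time after the last split so tip edges have
positive length; ultrametric by construction).  `simulate_traits` draws
multivariate-normal tip values whose among-tip covariance is the
lambda-transformed Brownian matrix and whose among-trait covariance is a
supplied correlation matrix.  `simulate_rate_estimates` scatters per-species
replicate estimates over log-uniform sampling times with an injectable
common time slope and curation flags.  `simulate_codon_alignment` perturbs
an ancestral sequence with synonymous changes at rate `theta_syn/2` per
synonymous site and non-synonymous sense changes at `omega * theta_syn/2`
per non-synonymous site, so pairwise piS ~ `theta_syn` and piN/piS ~ `omega`.

`reference_dataset(seed)` is the benchmark the pipeline is validated
against: 34 species (one engineered slow-rate, small-genome, low-GC
endosymbiont outlier), 12 species with 2-6 estimates each (69 curated
estimates), plus rows that correct curation must remove (two hypermutators,
one synonymous-only estimate, two estimates beyond 1500 years), a 12-species
mutation-rate table and a Yule tree.  Its defining property is that the
post-curation *sample* statistics are imposed exactly (to machine precision)
by construction: covariates are built from an orthonormal basis aligned with
the realised log rates and colored by the Cholesky factor of the target
correlation matrix, the within-species ANCOVA slope is set by a linear
adjustment absorbed by the group intercepts, the across-estimates time
correlation by a species-level shift solved with Brent's method, and the
outlier's covariates by root-finding on the full-sample correlations.
Affine rescaling to plausible units (genome size in Mb, GC %, piN/piS)
preserves the correlations exactly.

**What this does and does not show.**  Because the benchmark's statistics
are known exactly, recovering them end-to-end verifies the curation rules,
averaging, log transforms, outlier-exclusion bookkeeping and every statistic
in the pipeline.  It does not validate the biology of any particular real
compilation: the benchmark's traits are colored onto species independently
of the tree (so phylogenetic signal is weak by design — signal estimation is
validated separately by Brownian parameter-recovery tests), its noise
structure is Gaussian on the log scale, and no sequence evolution is
simulated down the tree.

## Known limitations

- The accumulation model excludes beneficial mutations, recurrent mutation
  at a site, recombination and diffusion-approximation solutions; it is a
  single-locus, discrete-generation model.
- Pagel's lambda is restricted to [0, 1] (some implementations allow the
  tree-specific upper bound above 1).
- piN/piS uses proportion counting without saturation correction and is
  meant for low within-species divergence.
- The ANCOVA assumes a common within-species slope; species-specific slopes
  are not modelled.
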