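# bacrate

Why do bacteria accumulate mutations at such different rates?  Estimates of
the *accumulation rate* — substitutions per site per year measured from
temporally sampled or dated isolates over months to ~1500 years — span more
than three orders of magnitude across species (from ~8.6x10^-9 in
*Mycobacterium leprae* to ~3.23x10^-5 in *Campylobacter jejuni*).  `bacrate`
is a toolkit for dissecting that variation, aimed at comparative
microbiologists and molecular evolutionists.  It provides:

- **A Wright-Fisher transition-matrix model** of how purifying selection
  makes rate estimates decline with sampling time.  A mutation of selection
  coefficient *s* enters a haploid population of *N* chromosomes as a single
  copy; each generation selection moves its frequency by
  *f' = (1-s)f / (1-sf)* and binomial drift resamples *N* chromosomes.  From
  the copy-number distribution *P(N, x, s, t)* the expected divergence is

  *D(N, s, t) = Σ_{v=1..t} Σ_x P(N, x, s, v) · x/N*,

  and the accumulation rate relative to neutral is
  *A(N, s, t) = D(N, s, t) / D(N, 0, t)* with *D(N, 0, t) = t/N*.  Fitness
  effects can be drawn from a gamma DFE (shape, mean *N·s*) and averaged
  across sampled mutations.  A seeded forward simulator provides an
  independent Monte-Carlo check.
- **Curation rules** for literature-style rate compilations: keep estimates
  sampled over at most 1500 years, all-sites estimates only, no hypermutator
  strains; average per species; analyse log10 rates.  Every exclusion is
  audited.
- **piN/piS** from codon alignments by Nei-Gojobori proportion counting.
- **Phylogenetic comparative methods**: Felsenstein's independent contrasts
  (with a low-variance contrast filter), Pagel's λ by maximum likelihood,
  Blomberg's K with a tip-permutation test, and sister-pair extraction for
  paired group tests.
- **Comparative statistics**: Pearson correlations, parallel-slopes ANCOVA
  for the within-species sampling-time effect, standardized multiple
  regression, Welch/paired t-tests, and the Fisher-z power analysis for the
  smallest detectable correlation.
- **Seeded synthetic-data generators** (Yule trees, λ-scaled Brownian traits
  with target correlations, replicate rate tables, toy codon alignments) and
  an engineered 34-species benchmark whose post-curation sample statistics
  are known exactly — the pipeline's ground truth.

## Worked example

The accumulation rate of selected mutations relative to neutral ones,
`python examples/wf_accumulation_curves.py`:

```
Gamma DFE (shape 0.5, 100 sampled mutations), A at t = 0.05 N:
  mean N*s = 10    ->  A = 0.867
  mean N*s = 100   ->  A = 0.537
  mean N*s = 1000  ->  A = 0.318

Monte-Carlo check, D(50, 0.1, 25): simulation 0.20012 +/- 0.00378,
transition matrix 0.19842
```

Even at 5% of *N* generations, selection with mean *N·s* = 1000 has already
cut the apparent rate to a third of the neutral expectation — which is why
estimates made over longer sampling windows look slower.

Curation plus cross-species correlations on the packaged synthetic benchmark,
`python examples/curate_and_correlate.py`:

```
curation: kept 69/74 estimates
  excluded Escherichia_coli: hypermutator strain
  excluded Helicobacter_pylori: site_class 'synonymous' (synonymous-only estimate)
  excluded Mycobacterium_leprae: sampling_time 2000.0 > 1500.0 years
  ...
34 species; rates span 1027-fold
log10 rate vs genome_size  (all species           ): r = -0.430, p = 0.0111, n = 34
log10 rate vs gc           (all species           ): r = -0.530, p = 0.0013, n = 34
log10 rate vs genome_size  (without B. aphidicola ): r = -0.570, p = 0.0005, n = 33
log10 rate vs gc           (without B. aphidicola ): r = -0.613, p = 0.0001, n = 33
log10 rate vs log10 sampling time (all estimates): r = -0.380, p = 0.0013, n = 69
```

The benchmark is generated with exactly these sample statistics, so any
deviation would expose a defect in the curation or correlation code.  The
other examples cover phylogenetic signal and contrasts
(`phylogenetic_signal.py`), codon diversity (`codon_diversity.py`) and the
full config-driven report (`full_report.py`).  The same capabilities are
exposed on the command line:

```bash
bacrate simulate --seed 0 --outdir data/synthetic_benchmark
bacrate curate --estimates data/synthetic_benchmark/rate_estimates.csv --outdir out/
bacrate wf-model --n 100 --dfe-shape 0.5 --dfe-mean-ns 100 --out curve.csv
bacrate report --estimates ... --traits ... --tree ... --outdir out/
```

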