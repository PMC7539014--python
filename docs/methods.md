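# Methods

## Barcode model

A barcode is an ordered pair of an 18 bp left module and an 18 bp right
module joined by a fixed 4 bp linker (default `ACGA`; real libraries do not
publish theirs, so it is carried in the library file and configurable). The
identifier `i:j` uses 1-based module indices. Libraries are sampled by
rejection so that modules on the same side are pairwise at Hamming
distance ≥ 5 (default): with ≤ 2 sequencing errors per half, the nearest
module is then unique, and two-mismatch mapping cannot be ambiguous.
Commercial libraries have tens of millions of barcodes; the simulator
defaults to 150 × 150 modules (22,500 composite barcodes), which is ample
for pools of ~20,000 clones while keeping exhaustive verification cheap.
Library size is a free parameter.

## Clonal dynamics

A `ClonePopulation` is a vector of per-clone cell counts `n_i ≥ 0` plus the
per-stage selection coefficients used so far. A stage transition is:

1. **Bottleneck** — a multinomial draw of `bottleneck_size` cells from the
   current relative abundances. This approximates sampling cells without
   replacement (transplantation, regression survival) and is exact in
   distribution when the population is much larger than the bottleneck;
   requesting every cell is the identity, and requesting more raises.
2. **Selective growth** — clone *i* grows by `exp((ln 2 + s_i)·g)` in
   expectation over `g` generations (ln 2 = one doubling per generation),
   realized as a Poisson draw. Clones at zero cells stay extinct. With
   `g = 0` the counts pass through unchanged.

Fitness is heritable: in `simulate_cohort`, each stage's `s_i` vector is
drawn once and shared by all replicate tumors, so the same clones dominate
every replicate — the signature that distinguishes selection of pre-existing
phenotypes from stochastic outgrowth. A stage may correlate its fitness
ranking with the previous stage's (`fitness_correlation`); the late
residual stage inherits the early stage's ranking outright, because the
clones that tolerate dormancy at four weeks are the ones still tolerating it
at eight.

Fitness scores (and the starting pool's clone-size scores) are standard
normal truncated at ±3.7 s.d. Untruncated normals occasionally hand one
clone an exponential growth advantage so extreme that a "primary tumor"
becomes near-monoclonal; real fitness advantages saturate, and replicate
tumors show a graded, reproducible spectrum of dominant clones rather than
jackpot winners. Truncation changes nothing for typical draws.

### Default scenario (the simulated study conditions)

| stage | bottleneck (cells) | generations | fitness s.d. | corr. to previous |
|---|---|---|---|---|
| pool | 17,000 clones × 5,000 cells, evenness 0.97 | — | — | — |
| primary | 1,000,000 | 10 | 0.27 | 0 |
| residual, 4 wk | 20,000 | 5 | 0.22 | 0.5 |
| residual, 8 wk | 5,000 | 4 | 0.20 | 1.0 |

Pool evenness maps to a log-normal clone-size spread with
σ = 40·(1 − evenness); at 0.97 the top clone holds ~0.2–0.4% of cells
(< 1%, as expected for a pool expanded in culture without strong selection).
Measured from 97,000 sampled cells per tumor (the number of cells a
barcoding PCR actually interrogates), this scenario yields, averaged over
seeds: primary tumors with ≈ 4,700 detected barcodes, top clone ≈ 7–8%, and
n50 ≈ 60; early residual n50 ≈ 16; late residual n50 ≈ 5 — the stage
profile the pipeline is designed around. `scaled_scenario` shrinks the
bottlenecks proportionally for fast tests without changing the trajectory's
shape.

### Recurrence routes

`denovo_driver` expands one uniformly chosen surviving clone to a target
fraction of cells (default 0.95) — an abstract fitness jump standing in for
a driver event such as an amplification; no sequence-level change is
modeled. `dominant_preexisting` expands the currently most abundant clone
likewise. `polyclonal` regrows every survivor with small i.i.d. log-normal
noise (s.d. 0.05), keeping the recurrent profile close to the pre-regression
one. Whether dominant recurrent clones pre-exist or arise de novo is
genuinely unresolved biology; both routes are provided rather than choosing.

## Read simulation

Reads are `left + linker + right` (40 bp) with i.i.d. substitution errors at
a configurable per-base rate (default 0.5%); substitutions never reproduce
the original base. Per-read quality is a clipped-normal mean (default Phred
37) with ±1 per-base jitter; a configurable fraction of reads is forced to
mean Phred < 30 (centred at 20, capped at 28) to exercise the QC filter.
Only the per-read mean matters downstream, so no positional error profile is
modeled; there is no PCR bias, duplicate, or indel model. Output is
byte-identical given the seed, and a truth table (read id → true barcode)
accompanies every FASTQ.

## Extraction

QC keeps reads with mean Phred ≥ 30 (checked first) and length exactly
40 bp. Halves map by exact seed indexing: three 6-mer seeds per 18-mer; a
half with ≤ 2 mismatches matches at least one seed exactly, so candidate
lookup plus full Hamming verification equals an exhaustive scan (the
`max_mismatches > 2` path falls back to the exhaustive scan explicitly).
Decisions taken where the protocol is silent:

- **Concordant-pair rule**: a read is assigned only if both halves map
  uniquely; discordant reads are discarded and tallied by reason
  (`left_unmapped`, `right_unmapped`, `both_unmapped`, `ambiguous`).
  Composite identity requires both halves; this is conservative and flagged
  for sensitivity analysis via `assign_reads`, which exposes per-read calls.
- **Ties** at the minimal distance are ambiguous, never broken arbitrarily —
  tie-breaking would inflate counts irreproducibly.
- **Non-ACGT characters** (N) count as mismatches at their position rather
  than invalidating the read.
- **Linker content is ignored** (it is removed before mapping); the count
  table drops barcodes with zero counts everywhere and keeps singletons
  (an optional `min_count` tightens this).
- Reads are taken in the given orientation only; the sequencing primer
  defines the strand.

## Metrics

Natural logarithms throughout (the choice of log base is a convention; ln
makes the JSD bound ln 2 explicit). The Jensen–Shannon **divergence** is
reported, not the square-root distance. JSD uses union supports with
0·ln 0 ≡ 0. `n50` sorts descending with ties broken by barcode id for
determinism; `n_barcodes_for_fraction` uses a 10⁻⁹ tolerance against
floating-point shortfall in cumulative sums. Rarefaction resamples
multinomially from the empirical frequencies — with replacement, so depths
above the observed total are meaningful — and a hypergeometric mode covers
classical without-replacement rarefaction. Architecture labels (clonal /
oligoclonal / polyclonal / intermediate) formalize qualitative tiers with
configurable thresholds (defaults: top ≥ 0.9; n50 ≤ 8; ≥ 1000 barcodes with
top < 0.1) and are reported alongside the thresholds used.

## Statistics

Welch's t-test is computed from first principles
(`t = (x̄−ȳ)/√(s²ₓ/nₓ+s²ᵧ/nᵧ)`, Welch–Satterthwaite df) with the two-sided
tail from the regularized incomplete beta function; it matches
`scipy.stats.ttest_ind(equal_var=False)` to 10⁻¹⁰ in tests. Two zero-variance
samples with equal means give p = 1 by convention; with unequal means,
t = ±∞ and p = 0. The two-way ANOVA interaction is fitted by OLS
(`value ~ C(a)·C(b)`, type-II sums of squares, via statsmodels), which
coincides with the classical balanced decomposition; noise-free additive
layouts return F = 0, p = 1 rather than 0/0. The factor layout intended for
stage analyses is A = stage pair, B = transition position, with replicate
tumors as observations. Group divergence comparisons use each unordered
matrix pair once (upper triangle, no diagonal) to avoid double counting. No
multiple-testing correction is applied anywhere, and reports state raw
p-values.

Design calculators use 6.6 pg per diploid mouse genome (the standard value,
overridable); rounding conventions (nearest 100/1000, one significant
figure) are explicit so report text matches a protocol's printed precision.

## What the generator does and does not emulate

It emulates: near-even starting pools with a bounded skew; stage-wise
bottlenecks with heritable selection producing reproducible dominant clones;
continued clone attrition through residual disease; three recurrence
architectures; substitution errors and a Q30-relevant quality mixture.

It does not emulate: PCR amplification bias or duplicates, indels,
positional error profiles, barcode-library sequence biases, genetic change
underlying fitness (drivers are abstract fitness jumps), recurrence timing,
or any transcriptional phenotype. Passing tests therefore demonstrate the
*pipeline's* correctness and the qualitative stage trajectory under the
stated generative model — not that real tumors obey the model.

## Problem sizes and numerical choices in the test suite

Unit tests run on 20×20-module libraries and populations of 50–17,000
clones. Pipeline-level checks use the full default scenario: six replicate
tumors, 10⁶ reads per sample at 0.5% substitution error for recovery
(binomial 99% envelopes per clone, exact intervals), 100 seeded runs for the
stage-trajectory direction, rarefaction depths 2×10³–10⁷, and 1,000
simulations for test calibration (null rejection in [0.03, 0.07] at
α = 0.05; Kolmogorov–Smirnov statistic < 0.05 against uniformity for the
ANOVA interaction p). The acceptance script averages stage profiles over ten
independent cohorts and scales read recovery to 3×10⁵ reads.

## Known limitations

- The multinomial bottleneck slightly overdisperses relative to true
  without-replacement sampling when the bottleneck approaches the population
  size; the identity shortcut at equality removes the worst case.
- Growth is Poisson per clone, so tiny clones can stochastically die even
  with positive fitness — intended, but it couples extinction to growth
  noise rather than modeling death explicitly.
- A pure log-normal pool cannot simultaneously reproduce a pool where
  ~17,000 of 17,000 clones are detected *and* only ~700 clones hold half the
  reads; the pool is calibrated to near-evenness with top clone < 1%, and
  its n50 lands near ~1,900 under the default skew.
- Cross-run variability of the extreme clone tail remains noticeable even
  with truncated fitness: occasional seeds produce primaries with n50 < 10.
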