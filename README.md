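# clonetrace

Analytics for lentiviral DNA-barcode lineage tracing in tumor models: from
raw 40 bp barcode reads to clone count tables to clonal-diversity and
divergence statistics across tumor stages — together with a synthetic-data
generator that simulates barcoded tumor populations through expansion,
regression, residual disease, and recurrence, so the whole pipeline can be
developed and tested at desk scale without any sequencing data.

## The problem

Cellular barcoding tags each founder cell with an inert, heritable DNA
barcode delivered by lentivirus at low multiplicity of infection, so that a
tumor's clonal composition can be read out by sequencing barcodes instead of
genomes. In regression/recurrence experiments this answers questions like:
how many clones seed a tumor, does therapy-driven regression bottleneck the
clone pool, do residual lesions keep losing clones, and does the recurrent
tumor descend from one clone or from many?

Here a barcode is a composite of a **left** and a **right 18-mer module**
separated by a fixed 4 bp linker, named `left:right` by 1-based module
indices (e.g. `8240:8518`). Reads are single-end 40 bp spanning the whole
cassette.

## What the package computes

**Extraction** (`clonetrace.extract`): reads with mean Phred < 30 or length
≠ 40 are discarded; each surviving read is split 18 + 4 + 18, the linker
removed, and each half mapped to its module list allowing ≤ 2 mismatches.
Mapping is *exact*: each 18-mer is partitioned into three 6-mer seeds, so a
half with ≤ 2 mismatches always has a clean seed (pigeonhole) — seed lookup
plus Hamming verification reproduces a brute-force scan. A read is assigned
`i:j` only if both halves map uniquely; ties are counted as ambiguous, never
broken arbitrarily. The result is a barcode × sample count table plus a
per-sample accounting (`assigned + discarded = total`, always).

**Diversity** (`clonetrace.divmetrics`), on clone frequencies
*p᷈* = (p₁…p_S):

- Shannon diversity index `H = −Σᵢ pᵢ ln pᵢ` (natural log; 0 for a
  monoclonal sample, ln S for S even clones);
- `n50`: the minimal number of most-abundant clones whose summed frequency
  reaches 50% of reads;
- top-clone fraction and cumulative abundance curves;
- Jensen–Shannon divergence
  `JSD(p, q) = ½ KL(p‖m) + ½ KL(q‖m)`, `m = ½(p+q)`, on the union of
  supports, bounded by ln 2 — the divergence itself is reported, not its
  square root;
- rarefaction: Shannon recomputed on reads resampled multinomially at fixed
  depths (depths above the observed total are allowed; a hypergeometric
  without-replacement mode exists for depths below it).

**Cohort statistics** (`clonetrace.cohort`): clone trajectories across
samples and stages, fold changes, Welch's unequal-variance t-test (with
Welch–Satterthwaite degrees of freedom), the two-way ANOVA interaction test,
and within- vs between-group JSD comparisons. P-values are never adjusted
for multiple testing; reports say so.

**Design calculators** (`clonetrace.designcalc`): clones per transduction
(`n·MOI`, or Poisson `n(1−e^(−MOI))`), cells per barcode, genome equivalents
per PCR input mass (6.6 pg per diploid mouse genome), cells analyzed per
sample.

**Simulator** (`clonetrace.simdata`): composite libraries with guaranteed
module separation, skewed clonal pools, bottleneck + selective-growth stage
transitions with heritable per-clone fitness, three recurrence routes
(de novo driver, dominant pre-existing clone, polyclonal reactivation), and
FASTQ generation with substitution errors and per-base qualities. All
randomness flows from explicit seeds; identical seeds give byte-identical
FASTQ.

## Worked example

`examples/03_diversity_metrics.py` simulates the default scenario — a
17,000-clone pool of 85 million cells, grafted through a 10⁶-cell bottleneck
into six replicate primary tumors with shared clone fitness, then regressed
through early (4-week) and late (8-week) residual-disease bottlenecks — and
profiles each stage from 97,000 sampled cells per tumor:

```
                barcodes  Shannon H      n50  top clone %
injected pool   13968.00       8.94  1858.00         0.24
primary tumors   4403.33       5.76    37.83        10.29
4-wk residual    1730.33       4.38     9.67        21.61
8-wk residual     549.67       3.62     5.50        23.56
```

Reading the table: primary tumor growth selects a subset of clones (detected
barcodes drop ~3-fold, half of all reads come from a few dozen clones, the
top clone holds ~10% of the tumor), and clone loss *continues* through
residual disease — by eight weeks, half the reads come from ~5 clones. The
accompanying rarefaction curve shows the Shannon index changes by < 0.5%
once a sample is subsampled at ≥ 2×10⁵ reads, so these stage differences are
not a sequencing-depth artifact. `examples/04_divergence_and_stats.py` adds
the divergence fingerprint: replicate primaries sit at JSD ≈ 0.02 nats from
one another but ≈ 0.50 nats from the injected pool — the same clones win in
every replicate.

Other examples: `01_design_numbers.py` (experiment sizing),
`02_simulate_and_extract.py` (FASTQ → count table round trip),
`05_recurrence_routes.py` (clonal vs polyclonal recurrence architectures).

A thin CLI mirrors the library: `clonetrace simulate | extract | diversity |
compare | design | run` (see `clonetrace --help`).

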