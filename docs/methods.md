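# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind mutaflux, and what the test suite does and does not show
about real data.

## Fluctuation analysis

### Model

A fluctuation experiment grows many parallel cultures from small inocula to
a common final size N_t and plates them under selection; the distribution of
resistant-colony counts across cultures identifies the mutation rate because
early ("jackpot") mutations produce large resistant clones. With `m` the
expected number of mutational events per culture, the count pmf is the
Luria–Delbrück distribution in its standard recursive form

    p_0 = e^(−m),    p_k = (m/k) · Σ_{i=0}^{k−1} p_i / (k − i + 1),

which corresponds to Poisson(m) events, each founding a clone whose final
size S satisfies P(S ≥ j) = 1/j — the size law of a mutation arising
uniformly in time in an exponentially growing population. The
Ma–Sandri–Sarkar MLE maximizes Σ_cultures log p_{k_i} over m.

### Estimation choices

- **Optimization.** The log-likelihood is maximized over ln m with a bounded
  scalar minimizer (Brent) on [ln 1e-6, ln(max count)]. A brute-force grid
  over m (step 0.001) serves as an independent oracle in the tests; the MLE
  must match its argmax to grid resolution on every tested input.
- **Confidence intervals.** Profile likelihood at a log-likelihood drop of
  1.92 (half the 95% χ²₁ quantile), found by bracketing and bisection on
  each side of m̂. Coverage is verified by simulation (≥90% over 200
  experiments of 12 cultures at m = 2). When every culture has zero
  colonies, m̂ = 0 and a one-sided upper bound solves n·m = 1.92.
- **Rate conversion.** μ = m / N_t, mutations per cell per division — the
  dominant convention in fluctuation analysis. The alternative m/(ln 2 · N_t)
  differs by a constant factor; consumers needing it can rescale.
- **Jackpots / censoring.** Counts at or above `censor_cap` (default policy:
  150, a countable-plate ceiling) are right-censored; their likelihood
  contribution is the cumulative tail mass P(count ≥ cap). This also bounds
  the pmf truncation index (k_max = largest observed count), keeping the
  O(k_max²) recursion cheap.
- **Partial plating.** When only a fraction ε of each culture is plated, the
  counts inform m_obs ≈ m·ε; the estimate is divided by ε before the rate
  conversion. This first-order scaling slightly inflates dispersion relative
  to the exact partial-plating likelihood (deliberately out of scope); at the
  ε ≈ 0.05 typical of these assays the bias on m̂ is small compared to the
  sampling error of a 12-culture experiment.

## Reporter-gene arithmetic

Mutant frequency divides resistant colonies by plating-efficiency-corrected
cells at risk. PDL = [ln N_t − ln(N₀·PE)]/ln 2 accumulates additively over
passages. Class error rates partition a total rate by catalog proportions;
splice/exon-loss events are reported as a third group rather than being
forced into the BPS/FS dichotomy. Repeat identical mutations within one PDL
are collapsed before frequency calculations (they reflect clonal expansion
of a single event), while the same change at different PDLs counts twice.

The Drake/Lynch extrapolation is evaluated exactly as written, with the
nonsense-detectability bracket x·(n_m+n_n)/n_n as a single multiplicative
factor. Evaluating it with the published HPRT1 constants (μ_L = 180×10⁻⁷,
f_BS = 79/126, L = 627, x = 3/64, n_m = 74, n_n = 5) gives 0.243×10⁻⁷ per bp
per duplication; published summaries of the same inputs round an
intermediate and print 0.23×10⁻⁷, so tests accept agreement within 10%.
Fold changes are reported to one decimal and per-doubling rates to the
nearest integer, matching conventional reporting precision.

## Variant filtering

Filters act on already-called SNVs: depth in both samples (exome 20x
normal / 30x tumor; WGS 10x/10x), absence from dbSNP138 / 1000 Genomes /
CG69 / ESP6500 (carried as INFO flags on the VCF so results cannot drift
with database versions), and VAF ≥ 0.05. Rejections are attributed to the
first failing criterion in the fixed order depth → database → VAF, making
tallies reproducible and additive. Multiallelic rows split per alt allele;
indels are counted at parse but never classified. Baseline subtraction
removes any (chrom, pos, ref, alt) key present in the early-passage call
set.

## Spectrum and signatures

All substitutions are mapped to the pyrimidine-containing strand (COSMIC
convention): 6 classes × 16 flank combinations = 96 bins, with opportunities
in 32 pyrimidine-centered trinucleotide bins. Opportunity normalization
divides each bin by its trinucleotide census and rescales so the total
equals the original count, keeping raw and normalized spectra on one axis
(rescaling to proportions or per-Mb rates is a trivial post-step).

Chi-square comparisons use the Yates continuity correction for 2×2 tables
(via scipy, whose correction is clipped so it never overshoots |O−E|). For
wider tables the correction generalizes per cell as max(|O−E|−0.5, 0)²/E — a
documented choice; no standard generalization exists. Categories with zero
combined count are dropped and degrees of freedom adjusted.

Signature refitting solves min ‖p − V w‖₂ s.t. w ≥ 0 by active-set NNLS
(scipy), where p is the spectrum as proportions and V the catalog matrix;
relative contributions are w/Σw. Cosine similarity against each catalog
vector is reported alongside. De novo signature extraction (NMF) is out of
scope — only refitting against a supplied catalog.

The bundled catalog (`data/synthetic_signatures.tsv`) is **synthetic**: four
hand-constructed probability vectors (a proofreading-deficiency-like
signature peaking at T[C>A]T and T[T>G]T, an MMR-loss-like NpCpG C>T
signature, an APOBEC-like T[C>T/G]W signature, and a flat background) in the
standard 96-row TSV layout. Real COSMIC signature files with the same layout
load unchanged.

## Synthetic data

The generators define the study conditions the tests run under:

- **Fluctuation counts**: Poisson(m) events per culture; clone sizes drawn as
  ⌊1/U⌋ (U uniform), capped at N_t; binomial thinning for partial plating.
  This continuous-growth lineage sampler matches the MSS pmf exactly — a
  synchronized-division variant was rejected because its single-clone sizes
  fall only on powers of two and visibly distort p_2, p_3, ... at the sample
  sizes used here. Defaults: 12 cultures, m = 2, N_t = 10⁷ (with 5×10⁵ of
  each culture plated when partial plating is exercised) — the scale of the
  HPRT1 assays this pipeline targets.
- **Genomes**: i.i.d. bases at 40% GC (human-like), default 100 kb in tests
  (large enough that every context bin has hundreds of candidate sites).
- **SNV catalogs**: each mutation's 96-bin is drawn from the stated signature
  mixture; a position with matching trinucleotide context is drawn without
  replacement from a precomputed per-context index (purine-centered sites
  receive the complementary change). Depths are Poisson (mean 36, a WGS-like
  depth); VAFs Beta(20,20) around 0.5 (clonal heterozygous). A baseline/late
  pair is the union construction, so subtraction recovers the novel set
  exactly.
- **Reporter catalogs**: one mutation per clone at a uniform ORF position
  with configurable class proportions; optional duplicate injection tests
  the uniqueness collapse.

What the synthetic data does **not** emulate: read-level error, mapping
artifacts, copy-number variation, subclonal structure, selection during
growth, phenotypic lag, and non-uniform genome composition. Passing tests
demonstrate the estimators and filters are correct under their stated
models, not that those models capture every property of a real sequencing
run; in particular real reporter-gene rates are known to undershoot
genome-wide rates several-fold for biological reasons the generator does
not model.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed (numpy `default_rng`; no
global state), and child seeds are spawned via `SeedSequence`. The test
suite uses 10⁵–10⁶ cultures for distributional checks, 200 experiments for
CI coverage, 10⁴ mutations for mixture recovery, and ~10⁵–2×10⁵ bp genomes —
sizes at which the statistical tolerances asserted (3 SD bands, 10%
recovery, ±0.05 contributions) are comfortably discriminating.

## Known limitations

- The exact partial-plating and differential-growth Luria–Delbrück variants
  and phenotypic-lag models are not implemented.
- The >2-category Yates correction is one reasonable generalization among
  several; for formal inference on wide tables prefer exact tests.
- Opportunity normalization assumes the supplied territory is the callable
  territory; no coverage-weighted census is computed.
- The CLI accepts only the formats described here (TSV counts/catalogs,
  uncompressed or bgzipped VCF via pysam, FASTA via pyfaidx).
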