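# mutaflux

Quantitative analysis of mutation rates and mutation spectra in hypermutator
human cell lines — the kind of experiment where DNA polymerase proofreading
and/or mismatch repair (MMR) are disabled, cells are grown through a defined
number of population doublings, and mutagenesis is measured both at a
selectable reporter gene (HPRT1 / 6-thioguanine) and genome-wide by
sequencing.

It is written for experimentalists and computational biologists who need to
go from raw assay outputs (colony counts, reporter-mutant catalogs, somatic
VCFs) to rates, genome-wide extrapolations and trinucleotide signature
attributions with explicit statistics, and it bundles seeded synthetic-data
generators so the entire chain is testable without any sequencing data.

## What it computes

**Fluctuation analysis (Luria–Delbrück / MSS-MLE).** Resistant-colony counts
across parallel cultures follow the Luria–Delbrück distribution; with `m`
the expected mutational events per culture, the count pmf satisfies

    p_0 = e^(−m),    p_k = (m/k) · Σ_{i=0}^{k−1} p_i / (k − i + 1)

and the Ma–Sandri–Sarkar maximum-likelihood estimator maximizes the product
of these probabilities over cultures (jackpot counts above a countable-plate
cap enter through the tail mass). The per-cell, per-division rate is
μ = m / N_t, and 95% confidence intervals come from the profile likelihood.

**Reporter-gene arithmetic.** Mutant frequency corrected for plating
efficiency, population doubling level PDL = [ln N_t − ln(N₀·PE)]/ln 2,
error-rate decomposition into base-pair substitutions (BPS) vs frameshifts
(FS), and the lacZ reversion error rate.

**Drake/Lynch genome-wide extrapolation.** A per-locus rate μ_L becomes a
per-base-pair, per-duplication substitution rate

    μ_BS = (μ_L · f_T · f_BS) / (L · f_L · [x (n_m + n_n)/n_n])

with the bracketed nonsense-detectability correction, from which predicted
genome-wide mutation counts over a given number of doublings follow.

**Variant filtering and baseline subtraction.** Somatic SNV calls are
retained only with sufficient depth in both samples (20x normal / 30x tumor
for exomes, 10x/10x for genomes), absence from common variant databases
(dbSNP138, 1000 Genomes, CG69, ESP6500), and variant-allele fraction ≥ 5%;
an early-passage (P0) call set is subtracted to isolate mutations that arose
during the defined doublings.

**Spectrum and signature analysis.** SNVs are binned into the 96
pyrimidine-strand trinucleotide contexts, optionally normalized by the
trinucleotide opportunity census of the callable territory, compared across
samples with Yates-corrected chi-square tests, and decomposed over a
signature catalog by non-negative least squares with per-signature cosine
similarities.

## Worked example

```python
from mutaflux import (
    SimulationConfig, simulate_fluctuation, LuriaDelbrueckModel,
    ExtrapolationParams, mu_bs, predicted_mutations, observed_vs_predicted,
)

# 12 parallel cultures grown to 1e7 cells, true m = 2 events/culture
cfg = SimulationConfig(seed=42, n_cultures=12, m=2.0, final_population=1e7,
                       censor_cap=150)
fit = LuriaDelbrueckModel(simulate_fluctuation(cfg)).fit()
print(fit.summary())
```

```
Luria-Delbrueck MSS-MLE fluctuation analysis
==============================================
cultures:            12
final population:    1e+07
plating fraction:    1
m_hat (per culture): 1.948
m 95% CI:            [1.064, 3.138]
rate (per cell/div): 1.948e-07
rate 95% CI:         [1.064e-07, 3.138e-07]
log-likelihood:      -39.3553
```

The estimator recovers the generating rate (1.95 vs 2.0 events per culture,
i.e. 1.9×10⁻⁷ per cell per division at N_t = 10⁷) with a CI that covers the
truth. Feeding a measured HPRT1 rate of 180×10⁻⁷ through the extrapolation:

```python
params = ExtrapolationParams(mu_L=180e-7, f_T=1.0, f_BS=79/126, L=627,
                             f_L=1.0, x=3/64, n_m=74, n_n=5)
mu = mu_bs(params)                                  # 2.43e-08 per bp per doubling
n_pred = predicted_mutations(mu, 2.8e9, 13.9)       # ~946 mutations
fold = observed_vs_predicted(5282, n_pred)          # 5.6-fold excess observed
```

A genome-wide observation of 5,282 new SNVs over ~14 doublings therefore
exceeds the reporter-based prediction several-fold — the signature of
mutagenesis the reporter gene under-samples.

There is also a CLI (`mutaflux --help`) with subcommands for each stage
(`estimate-rate`, `extrapolate`, `filter-variants`, `subtract-baseline`,
`classify-spectrum`, `compare-spectra`, `refit-signatures`, `simulate-*`)
and an end-to-end `run-pipeline` that writes a JSON summary.

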