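# mutvar

Quantifying influences on the intragenomic heterogeneity of the human
polymorphism probability: how much of the variance in SNV (single
nucleotide variant) density is attributable to **meiotic recombination**,
and how much to **k-mer sequence context**?

The package implements, and exercises end to end on synthetic data with
known ground truth, the two bespoke inference procedures such a study
needs:

1. **Recombination.** Per-10-kb-block SNV densities are regressed on
   standardized per-block recombination rates. Because both quantities are
   spatially autocorrelated along the genome, the residuals are modelled as
   an ARMA(p, q) process and the slope β, intercept α and the p+q ARMA
   coefficients are estimated **jointly** by MCMC:

       density_i = α + β · rate_i + ε_i ,   ε ~ ARMA(p, q)

   with the order (p, q) chosen by AIC over a grid (p ≤ 10, q ≤ 4, p > 0)
   after an augmented Dickey–Fuller stationarity check of the OLS
   residuals. Derived statistics: σ²rec (total density variance minus mean
   squared regression residual; negative for worse-than-flat fits), R²,
   ρ̂ = (m̄ − α)/m̄ (the fraction of SNVs attributable to recombination),
   and ρ̂ · μ/χ, the implied number of mutations per crossover (μ, χ =
   genome-wide mutation and crossover rates per bp per generation).

2. **Context.** Every (k-mer, mutation direction) cell gets a binomial
   count pair — trials nᶜ (occurrences of the k-mer, counted exactly) and
   successes sᶜ (qualified SNVs mutating the central base) — and a
   conjugate Beta(1 + s, 1 + n − s) posterior. Posterior draws of the
   context-weighted variance

       σ²ₖ = Σ_c p_c (m_c − m̄)² ,   m̄ = Σ_c p_c m_c

   are formed by drawing each cell's rate independently. Variants enter
   only if biallelic with a known ancestral allele and no other variant
   within 4 bp on either side, oriented to the annotated gene strand. The
   statistic is also computed per mutation direction, marginalised over the
   central base (flank-only influence), conditioned on CpG dinucleotides,
   and compared across strand-complementary direction pairs (asymmetric if
   the 97.5th percentile of one posterior lies below the 2.5th of the
   other).

Block exclusions (no-SNV blocks, map-missing blocks and their neighbors)
are imputed by Last Observation Carried Forward from the 5′ side so the
ARMA lag structure stays intact.

## Layout

- `src/mutvar/` — the library: `genomic_io` (rmap/VCF/BED/FASTA), `filters`
  (qualification, exclusions, LOCF), `regression` (OLS, ADF, AIC order
  selection, ensemble-MCMC ARMA fit), `context` (counting, beta posteriors,
  variance statistics), `synthetic` (ground-truth generators), `cli`.
- `analysis/01..04_*.py` — numbered drivers that simulate the study data,
  fit the recombination model, measure context variance, and test strand
  asymmetry, writing tables under `results/`.
- `scripts/acceptance.py` — recomputes all headline quantities from
  scratch (see below).

## Worked example

```
$ python analysis/01_simulate_data.py --seed 1
$ python analysis/02_recombination_fit.py --seed 1
2000 blocks; 73 excluded (3.6%), LOCF applied
ADF: statistic -21.40, p=0 -> stationary
residual ACF lags 1-5: [0.563, 0.299, 0.145, 0.084, 0.059]
AIC grid chose ARMA(2, 0)
slope 0.00706 [0.00695, 0.00716] (truth 0.007)
intercept 0.02572 [0.02536, 0.02610] (truth 0.026)
P(slope<=0) = 0.0000; sigma2_rec = 8.13e-05; R2 = 0.804
rho_hat = 22.33% of SNVs attributed to recombination; 0.229 mutations per crossover
```

The 95% credibility intervals cover the generating slope and intercept;
the residual ACF shows why an iid-error model would be wrong here, and the
AIC grid picks a close AR approximation of the generating ARMA(1, 1)
noise. ρ̂ is large only because the synthetic slope is strong relative to
the baseline density.

```
$ python analysis/03_context_variance.py --seed 1
82143 of 100520 variants qualify (biallelic, ancestral known, no neighbor within 4 bp)
k=1: sigma2 = 5.05e-05 [4.89e-05, 5.21e-05]
k=3: sigma2 = 0.000354 [0.000346, 0.000362]; marginalised 7.85e-05; CpG share 0.87
k=5: sigma2 = 0.000361 [0.000353, 0.000369]; marginalised 8.05e-05; CpG share 0.87
```

The genome was generated with a 10× CpG effect and no effects beyond the
immediate neighbors, and the statistics read that back: σ²₃ ≫ σ²₁, almost
no further gain at k = 5, a small flank-only (marginalised) component, and
CpG contexts carrying ~87% of σ²₃.

```
$ python analysis/04_strand_asymmetry.py --seed 1
asymmetric-process: 1 of 6 pairs called asymmetric (T>C / A>G)
symmetric-process: 0 of 6 pairs called asymmetric
```

A CLI is also installed (`mutvar simulate-blocks | simulate-genome |
filter-variants | fit-recombination | context-variance | strand-asymmetry
| report`); every output gets a JSON provenance sidecar.

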