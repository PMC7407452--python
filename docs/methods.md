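# Methods

## The model of mutation heterogeneity

Each genomic site is assumed to carry a fixed probability *m* of being
polymorphic for an SNV, with mutation events independent across sites.
SNV density — qualified SNV count over eligible sites — is the observable
surrogate for *m*. Two sources of heterogeneity in *m* are quantified
separately: the local recombination rate (an *event* rate averaged over
10-kb blocks) and the k-mer sequence context of the site (a *state*).
Both analyses are Bayesian so that uncertainty in the derived variance
statistics is carried through to the end instead of being collapsed into
plug-in point estimates.

### Recombination: linear regression with ARMA errors

For one chromosome-like unit the model is

    density_i = α + β · rate_i + ε_i,    ε ~ ARMA(p, q), normal innovations,

where `rate_i` is the standardized recombination rate of block *i*
(dimensionless; one unit corresponds to `mean_cM_per_block` centimorgans,
default 0.0116 cM for a 10-kb block). Fitting proceeds in stages:

1. **OLS baseline** for point estimates and residuals.
2. **Stationarity** of the residuals via the augmented Dickey–Fuller test
   (verdict: p < 0.05); stationarity is what licenses an ARMA
   representation of the residual process at all.
3. **Order selection** by AIC over the grid 1 ≤ p ≤ p_max (default 10),
   0 ≤ q ≤ q_max (default 4). Non-converged fits are excluded from the
   ranking. The selection object exposes lower-ranked orders because the
   best-AIC model occasionally destabilises the subsequent MCMC; the
   sampler retries them automatically when its convergence diagnostic
   fails.
4. **Joint MCMC** over (α, β, φ₁..φ_p, θ₁..θ_q, log σ) with the exact
   Gaussian ARMA-regression likelihood. The likelihood is evaluated by a
   Kalman filter over the Harvey state-space form with exact stationary
   initialization, implemented in numba for speed (~0.05 ms per
   evaluation at n = 1,000); the test suite asserts agreement with the
   statsmodels Kalman filter to 1e-6, so the fast path is cross-checked
   against an independent implementation on every run.

**Priors** (the data sets the scale; nothing in the procedure depends on
external tuning): α, β ~ Normal centered on the OLS estimates with sd =
10 × the OLS standard errors; φ, θ flat on the stationary/invertible
region (rejected outside it); σ half-normal with scale 10 × the OLS
residual sd, sampled as log σ with the Jacobian included.

**Sampler.** Affine-invariant ensemble MCMC (emcee) with a
differential-evolution move mixture (80% DEMove, 20% DESnookerMove),
16 walkers, 1,500 burn-in and 2,000 retained steps per walker (32,000
posterior draws), initialised by overdispersing walkers around the
maximum-likelihood fit at roughly posterior scale. Convergence requires
the rank-normalised potential scale reduction, computed over walkers
grouped into 4 pseudo-chains, to be < 1.01 for every parameter; failure
triggers the order fallback described above.

**Derived statistics** (all computed per posterior draw, then
summarized):

- residuals are the *regression* residuals `density − (α + β·rate)`, not
  the ARMA-whitened innovations — σ²rec measures the variance explained
  by recombination alone;
- σ²rec = Var(density) − mean(residual²). "Mean" rather than "sum"
  squared residual keeps σ²rec commensurate with Var(density) (a sum
  would scale with n); σ²rec < 0 (worse-than-flat fit) is reported as-is;
- R² = σ²rec / Var(density);
- ρ̂ = (m̄ − α)/m̄ with m̄ the mean density over observed blocks
  (pre-LOCF by default; `mbar_after_locf` switches, since either reading
  is defensible and the difference is below a percent at realistic
  missingness);
- mutations per crossover = ρ̂ · μ/χ with μ = 1.19e-8 mutations/bp/gen
  and χ = 1.16e-8 crossovers/bp/gen by default;
- slope per cM = β / mean_cM_per_block, and in mutation-rate units
  × μ/m̄. The deliberately naive slope-based mutations-per-crossover
  estimate (slope per Mb per cM divided by 0.01) is provided for
  comparison only: it attributes all recombination-associated mutations
  to the current generation's crossovers and overstates the per-event
  rate by orders of magnitude.

**Blocks and imputation.** Excluded are blocks with no SNVs, blocks the
map flags as unsequenced, and the single block on each side of the
latter ("adjacent" read minimally). Excluded blocks take their 5′
nearest retained neighbor's rate and density (LOCF), preserving the lag
grid; excluded blocks at the series head have no 5′ neighbor and are
dropped (logged). An excluded fraction above 5% logs a warning. Shadow
fields retain pre-imputation values; m̄ uses them.

Per-direction analyses reuse the machinery on a view of the series whose
density is that direction's density, with the count of ancestral-base
sites in the block as denominator — per-direction densities like 0.0247
for C→T are per-ancestral-C-site, not per-bp, which is the only reading
on which they are commensurate with the overall density.

### Context: beta-posterior weighted variance

For context size k (odd), every (k-mer, direction) cell is a binomial:
trials = exact occurrences of the k-mer centered on maskable sites
(windows crossing interval edges or containing N are skipped;
minus-strand intervals counted on the reverse complement), successes =
qualified SNVs with that oriented context and direction. With a
Beta(1, 1) prior the posterior is Beta(1+s, 1+n−s). Draws of

    σ²ₖ = Σ_c p_c (m_c − m̄)²,   p_c = trials_c / Σ trials

are accumulated streaming over cells (per-draw Σ p·m and Σ p·m², so k = 7
fits in memory). Cells with zero variants keep the uniform posterior —
exactly the variance-inflation hazard the method is known for — and
their prevalence above 1% of cells logs a warning.

Choices where the design was genuinely open:

- **Per-direction center.** The per-direction statistic σ²ₖ(a→b)
  defaults to deviations around the direction-specific weighted mean
  m̄_{a→b}; only that convention makes each σ²ₖ(a→b) a variance. The
  alternative "literal" convention (centering on m̄_a, the all-direction
  rate of central base a) is available as `mean_convention="literal"` /
  `--eq1-literal`, and mixes the direction's spread with its offset from
  the total rate.
- **Marginalisation** pools counts over the four central bases into bins
  indexed by the flanking (k−1)-mer, isolating the influence of the
  flanks alone; variance is then the weighted variance over bins.
- **CpG conditioning** defaults to the standard CpG definition (central
  C with 3′ G, central G with 5′ C); `--cpg-orientation mirrored`
  gives the mirrored reading. The CpG contribution is
  Σ_{c∈CpG} p_c (m_c − m̄)² with m̄ the full mean, and the share is its
  per-draw ratio to σ²ₖ.
- **Spacing rule.** A variant is disqualified iff another variant (of
  any kind, including ones themselves disqualified) lies at distance
  ≤ 4 bp; `min_separation` exposes the alternative strict-inequality
  reading.
- **Strand asymmetry** between the posteriors of a strand-complementary
  direction pair is declared when the 97.5th percentile of one lies
  below the 2.5th percentile of the other.
- **Per-cell random streams** are counter-based (keyed on the cell's
  integer code via `SeedSequence(seed, spawn_key=(key,))`), so one
  cell's draws are invariant to which other cells exist; marginalised
  bins use a disjoint key space. This makes every posterior bit-for-bit
  reproducible under a fixed seed regardless of chunking.

## Synthetic data

The generators produce the study's inputs with known ground truth and
write them through the same file formats the real data would use (rmap
dialect, FASTA, VCF with AA, BED6), so the I/O path is exercised rather
than bypassed.

- `simulate_blocks`: density = α + β·rate + ARMA(p, q) noise, rates from
  a gamma background (shape 0.6, mean 1, matching the skew of
  standardized per-block recombination rates) with an optional hotspot
  component; SNV counts are binomial over the 10-kb block (the count
  nature of the data is what breaks iid-error OLS inference in the first
  place). Defaults: 0.026 intercept, 0.007 slope per standardized rate
  unit, ARMA(1, 1) φ = 0.5, θ = 0.3, innovation sd 0.003 — magnitudes
  shaped like human autosome block series, with a deliberately strong
  slope so recovery tests have signal. Missingness is injected in runs
  (geometric lengths, mean 2) because unsequenced map regions span
  consecutive blocks.
- `simulate_genome`: iid base composition; each site's polymorphism
  probability and direction distribution looked up from a parametric
  (4^k × direction) rate table — per-direction base rates with a
  transition-heavy spectrum, a CpG multiplier on C→T with 3′ G and G→A
  with 5′ C, and arbitrary neighbor effects; variants drawn
  independently per site; multiallelic sites and ≤4-bp cluster pairs
  injected afterwards to exercise the filters. The truth table (rates
  actually used, plus realized and theoretical context weights at any k)
  feeds the exact-variance oracles.

What the generator does **not** emulate — linkage and coalescent noise,
selection, gBGC, non-stationary base composition, finite-sample ancestral
misidentification — bounds what passing tests show: they demonstrate that
the estimators recover the parameters of this model, not that the model
captures every force acting on real polymorphism data. One consequence
is visible and intended: the 4-bp spacing filter thins successes while
trials still count all sites, so filtered σ²ₖ estimates sit below the
generative table's variance by roughly the squared retention fraction
(~35% at the default densities); the unfiltered estimate recovers the
generative value, and the acceptance report carries both.

## Problem sizes and numerical checks

Study sizes were chosen so the full suite runs in a few minutes on one
CPU: calibration uses 20 replicates of 1,000-block series (the
ARMA-likelihood evaluations dominate); order-selection identifiability
uses n = 20,000 residuals on a (p ≤ 3, q ≤ 2) grid; CpG-multiplier
recovery uses a 10-Mb genome; strand-asymmetry uses 20 seeds per
condition at 1 Mb. Observed outcomes at those sizes: Bayes 95% intervals
covered the true intercept in 20/20 and the slope in 18/20 replicates
while iid-error OLS covered the intercept in 14/20; CpG ratio recovered
at 9.6 for a multiplier of 10; strand-asymmetry verdicts correct in
20/20 (asymmetric condition) and 19/20 (symmetric condition).

Degenerate inputs are errors, not silences: constant rates (singular
design), zero-variance residual series, all-excluded block series, empty
context tables, k even, >1% ancestral-base mismatches. Ties in AIC are
broken by grid order (lower p, then lower q, first).

## Known limitations

- The ensemble sampler's walkers are not independent chains; the
  potential-scale-reduction diagnostic over walker groups is a practical
  convergence check, not a guarantee.
- The AIC grid frequently selects a close AR approximation (e.g. AR(2))
  of a true ARMA(1, 1) process at moderate n; this is a property of AIC,
  and posterior inference for α and β is insensitive to it.
- The optional rate measurement-error term (`rate_error_sd`) perturbs
  the design variable rather than modelling errors-in-variables
  generatively; it exists as a robustness check and is off by default.
- Genome-wide pooled fits (common α, β across chromosomes) are not
  provided as a first-class path: with per-chromosome heterogeneity a
  pooled intercept is not interpretable, and per-chromosome fits are the
  supported analysis.
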