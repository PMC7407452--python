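"""Synthetic block series and genomes with known ground truth.

Every downstream estimator gets a parameter-recovery test from here: the
block simulator draws densities from the same linear-plus-ARMA model the
regression fits (with binomial SNV counts, matching the count nature of the
data rather than the Gaussian OLS idealisation), and the genome simulator
assigns each site a polymorphism probability looked up from a k-mer context
rate table (base rates per mutation direction, a CpG multiplier, and
arbitrary neighbor effects), then emits the genome/variants/regions through
the same file formats the real data would arrive in.

All randomness flows from a single seed through numpy ``SeedSequence``
spawning, so individual stages are reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from statsmodels.tsa.arima_process import ArmaProcess

from ._util import (BASE_TO_CODE, BASES, DIRECTIONS, kmer_codes, seq_to_codes,
                    spawn_rng)
from .filters import BlockSeries
from .genomic_io import RecombinationMap, RegionMask, VariantRecord

import pandas as pd

# sub-stream labels
_RATES, _EPS, _COUNTS, _MISSING = 1, 2, 3, 4
_SEQ, _POLY, _DIR, _MULTI, _CLUSTER = 11, 12, 13, 14, 15


# ---------------------------------------------------------------------------
# block series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateMixture:
    """Background gamma recombination rates plus an optional hotspot component."""

    shape: float = 0.6
    scale: float = 1.0 / 0.6  # mean 1, like standardized deCODE rates
    hotspot_weight: float = 0.0
    hotspot_multiplier: float = 10.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        rates = rng.gamma(self.shape, self.scale, n)
        if self.hotspot_weight > 0:
            hot = rng.random(n) < self.hotspot_weight
            rates[hot] *= self.hotspot_multiplier
        return rates


@dataclass
class BlockSimParams:
    """Generative parameters for a per-block rate/density series.

    ``intercept_true`` is the SNV density at zero recombination and
    ``slope_true`` the density increase per standardized rate unit; defaults
    mirror the magnitudes seen on human autosomes (densities near 0.028,
    standardized rates of order 1).
    """

    n_blocks: int = 1000
    intercept_true: float = 0.026
    slope_true: float = 0.007
    arma_order: tuple[int, int] = (1, 1)
    ar_coeffs: tuple[float, ...] = (0.5,)
    ma_coeffs: tuple[float, ...] = (0.3,)
    noise_sd: float = 0.003
    rate_distribution: RateMixture = field(default_factory=RateMixture)
    missing_fraction: float = 0.0
    block_size: int = 10_000
    binomial_counts: bool = True
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        p, q = self.arma_order
        if len(self.ar_coeffs) != p or len(self.ma_coeffs) != q:
            raise ValueError("coefficient lists inconsistent with arma_order")
        if p and not ArmaProcess.from_coeffs(self.ar_coeffs, self.ma_coeffs).isstationary:
            raise ValueError("AR polynomial is not stationary")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0,1)")


def simulate_blocks(params: BlockSimParams) -> tuple[BlockSeries, dict]:
    """Draw a block series density_i = a + b*rate_i + eps_i, eps ~ ARMA(p,q).

    SNV counts are then drawn binomially over ``block_size`` sites and
    re-normalized to densities. The truth record carries all parameters, the
    realized noise, and the pre-binomial model densities.
    """
    p, q = params.arma_order
    rng = spawn_rng(params.seed, _RATES)
    rates = params.rate_distribution.sample(params.n_blocks, rng)

    eps_rng = spawn_rng(params.seed, _EPS)
    if params.noise_sd == 0:
        eps = np.zeros(params.n_blocks)
    elif p == 0 and q == 0:
        eps = eps_rng.normal(0.0, params.noise_sd, params.n_blocks)
    else:
        proc = ArmaProcess.from_coeffs(params.ar_coeffs, params.ma_coeffs)
        burn = 50 * max(p, q, 1)
        eps = proc.generate_sample(
            params.n_blocks, scale=params.noise_sd, burnin=burn,
            distrvs=eps_rng.standard_normal)

    model_density = params.intercept_true + params.slope_true * rates + eps
    if model_density.min() < 0 or model_density.max() > 1:
        raise ValueError("model density outside [0,1]; adjust parameters")

    if params.binomial_counts:
        cnt_rng = spawn_rng(params.seed, _COUNTS)
        counts = cnt_rng.binomial(params.block_size, model_density)
        density = counts / params.block_size
    else:
        density = model_density

    series = BlockSeries(
        chrom=params.chrom,
        start=np.arange(params.n_blocks, dtype=np.int64) * params.block_size,
        rate=rates,
        density=density,
        block_size=params.block_size,
    )
    truth = {"params": params, "eps": eps, "model_density": model_density}
    if params.missing_fraction > 0:
        series = inject_missing(series, params.missing_fraction, params.seed)
    return series, truth


def inject_missing(series: BlockSeries, fraction: float, seed: int,
                   mean_run: float = 2.0) -> BlockSeries:
    """Flag random runs of blocks as map-missing (geometric run lengths).

    Missingness comes in runs because unsequenced map regions span multiple
    consecutive blocks. Original values are retained in the shadow fields.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0,1)")
    n = len(series)
    missing = series.rate_missing.copy()
    if fraction > 0:
        rng = spawn_rng(seed, _MISSING)
        start_prob = fraction / mean_run
        starts = np.flatnonzero(rng.random(n) < start_prob)
        lengths = rng.geometric(1.0 / mean_run, len(starts))
        for s, ln in zip(starts, lengths):
            missing[s : s + ln] = True
    return BlockSeries(
        chrom=series.chrom,
        start=series.start.copy(),
        rate=series.rate.copy(),
        density=series.density.copy(),
        block_size=series.block_size,
        rate_missing=missing,
        direction_density={d: a.copy() for d, a in series.direction_density.items()},
        shadow_rate=series.rate.copy(),
        shadow_density=series.density.copy(),
    )


def series_to_rmap(series: BlockSeries, mean_cM_per_block: float = 0.0116) -> RecombinationMap:
    """Express a simulated series as a recombination map (NaN where missing)."""
    blocks = pd.DataFrame({
        "chrom": series.chrom,
        "start": series.start,
        "end": series.start + series.block_size,
        "rate": np.where(series.rate_missing, np.nan, series.rate),
        "missing": series.rate_missing,
    })
    return RecombinationMap(blocks, series.block_size, mean_cM_per_block)


# ---------------------------------------------------------------------------
# context rate model & genome simulation
# ---------------------------------------------------------------------------

def _default_direction_rates() -> dict[tuple[str, str], float]:
    # transition/transversion mix shaped like the human intronic spectrum
    rates = {}
    for d in DIRECTIONS:
        transitions = {("C", "T"), ("G", "A"), ("T", "C"), ("A", "G")}
        rates[d] = 0.008 if d in transitions else 0.0015
    return rates


@dataclass(frozen=True)
class NeighborEffect:
    """Multiply the rate (of one direction, or all) when the base at
    ``offset`` from the mutating site equals ``base``."""

    offset: int
    base: str
    multiplier: float
    direction: tuple[str, str] | None = None


@dataclass
class ContextRateModel:
    """Per-(k-mer, direction) polymorphism probabilities, parametrically.

    The table is built from per-direction base rates, an optional CpG
    multiplier (applied to C->T with 3' G and, strand-symmetrically, G->A
    with 5' C), and arbitrary neighbor effects. ``k`` is the context size
    the model is expressed at.
    """

    k: int = 3
    direction_rates: dict[tuple[str, str], float] = field(
        default_factory=_default_direction_rates)
    cpg_multiplier: float = 1.0
    neighbor_effects: tuple[NeighborEffect, ...] = ()

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or self.k < 1:
            raise ValueError("k must be odd and >= 1")
        h = (self.k - 1) // 2
        if self.cpg_multiplier != 1.0 and self.k < 3:
            raise ValueError("CpG multiplier requires k >= 3")
        for eff in self.neighbor_effects:
            if eff.offset == 0 or abs(eff.offset) > h:
                raise ValueError(f"neighbor effect offset {eff.offset} outside context of size {self.k}")

    def rate_table(self) -> np.ndarray:
        """(4**k, 4) array: probability of each (context, to-base) mutation."""
        k, h = self.k, (self.k - 1) // 2
        n = 4 ** k
        codes = np.arange(n)
        digits = np.empty((n, k), dtype=np.uint8)
        tmp = codes.copy()
        for j in range(k - 1, -1, -1):
            digits[:, j] = tmp % 4
            tmp //= 4
        central = digits[:, h]
        table = np.zeros((n, 4))
        for (a, b), rate in self.direction_rates.items():
            ai, bi = BASE_TO_CODE[a], BASE_TO_CODE[b]
            row = central == ai
            mult = np.ones(n)
            if self.cpg_multiplier != 1.0:
                if (a, b) == ("C", "T"):
                    mult[digits[:, h + 1] == BASE_TO_CODE["G"]] = self.cpg_multiplier
                elif (a, b) == ("G", "A"):
                    mult[digits[:, h - 1] == BASE_TO_CODE["C"]] = self.cpg_multiplier
            for eff in self.neighbor_effects:
                if eff.direction is not None and eff.direction != (a, b):
                    continue
                mult = np.where(digits[:, h + eff.offset] == BASE_TO_CODE[eff.base],
                                mult * eff.multiplier, mult)
            table[row, bi] = rate * mult[row]
        if table.sum(axis=1).max() > 1:
            raise ValueError("total per-site polymorphism probability exceeds 1")
        return table


@dataclass
class GenomeSimParams:
    """Generative parameters for a context-dependent polymorphic genome."""

    length: int = 1_000_000
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    rate_model: ContextRateModel = field(default_factory=ContextRateModel)
    fraction_multiallelic: float = 0.0
    cluster_rate: float = 0.0  # expected injected clustered pairs per kb
    gene_annotation_spec: tuple[tuple[int, int, str, str], ...] | None = None
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.base_frequencies, dtype=float)
        if f.min() < 0 or abs(f.sum() - 1) > 1e-9:
            raise ValueError("base_frequencies must be non-negative and sum to 1")
        if not 0 <= self.fraction_multiallelic < 1:
            raise ValueError("fraction_multiallelic must be in [0,1)")


@dataclass
class TruthContextTable:
    """Ground-truth per-(context, direction) probabilities and weights.

    ``probs`` is the (4**k, 4) rate table actually used; ``weights`` are the
    realized k-mer proportions within the emitted region mask. Theoretical
    (independent-site) weights at any odd k are available via :meth:`at_k`,
    which expands or pools the model table — the infinite-data limit used by
    the exact-variance oracles.
    """

    k: int
    probs: np.ndarray
    weights: np.ndarray
    base_frequencies: tuple[float, float, float, float]

    def theoretical_weights(self, k: int) -> np.ndarray:
        f = np.asarray(self.base_frequencies)
        w = np.ones(1)
        for _ in range(k):
            w = np.repeat(w, 4) * np.tile(f, len(w))
        return w

    def at_k(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(probs, theoretical weights) of the truth model at context size k."""
        if k % 2 == 0 or k < 1:
            raise ValueError("k must be odd and >= 1")
        km, probs = self.k, self.probs
        if k >= km:
            # expand: each larger context inherits its central k_m-mer's rates
            pad = (k - km) // 2
            n = 4 ** k
            codes = np.arange(n)
            central = (codes // 4 ** pad) % 4 ** km
            return probs[central], self.theoretical_weights(k)
        # pool: weighted average of rates over flanks beyond size k
        pad = (km - k) // 2
        wk = self.theoretical_weights(km)
        codes = np.arange(4 ** km)
        sub = (codes // 4 ** pad) % 4 ** k
        denom = np.bincount(sub, weights=wk, minlength=4 ** k)
        pooled = np.zeros((4 ** k, 4))
        for t in range(4):
            pooled[:, t] = np.bincount(sub, weights=wk * probs[:, t], minlength=4 ** k)
        pooled /= denom[:, None]
        return pooled, self.theoretical_weights(k)


def simulate_genome(params: GenomeSimParams) -> tuple[
        dict[str, str], RegionMask, list[VariantRecord], TruthContextTable]:
    """Simulate an ancestral genome and independent per-site polymorphisms.

    Each site's polymorphism probability and direction distribution are
    looked up from the context rate table given its realized k-mer; the
    requested fractions of multiallelic and clustered variants are injected
    afterwards (clusters deliberately violate the 4-bp spacing assumption so
    the qualification filters have something to remove).
    """
    k = params.rate_model.k
    h = (k - 1) // 2
    L = params.length
    f = np.asarray(params.base_frequencies, dtype=float)

    seq_rng = spawn_rng(params.seed, _SEQ)
    codes = seq_rng.choice(4, size=L, p=f).astype(np.uint8)
    seq = bytes(np.frombuffer(b"ACGT", dtype=np.uint8)[codes]).decode("ascii")

    table = params.rate_model.rate_table()
    site_kmers, valid = kmer_codes(codes, k)  # windows centered at h..L-h-1
    centers = np.arange(h, L - h)
    total_rate = np.where(valid, table.sum(axis=1)[site_kmers], 0.0)

    poly_rng = spawn_rng(params.seed, _POLY)
    hit = poly_rng.random(len(centers)) < total_rate
    hit_pos = centers[hit]
    hit_kmer = site_kmers[hit]

    # choose derived base from per-context direction distribution
    dir_rng = spawn_rng(params.seed, _DIR)
    probs = table[hit_kmer]
    cum = np.cumsum(probs, axis=1)
    cum /= cum[:, -1:]
    u = dir_rng.random(len(hit_pos))
    to_code = (u[:, None] > cum).sum(axis=1)

    records: dict[int, VariantRecord] = {}
    anc_codes = codes[hit_pos]
    for pos, ac, tc in zip(hit_pos, anc_codes, to_code):
        anc, der = BASES[ac], BASES[tc]
        records[int(pos)] = VariantRecord.build(params.chrom, int(pos), anc, (anc, der))

    if params.fraction_multiallelic > 0 and records:
        multi_rng = spawn_rng(params.seed, _MULTI)
        for pos in list(records):
            if multi_rng.random() < params.fraction_multiallelic:
                v = records[pos]
                others = [b for b in BASES if b not in v.alleles]
                extra = others[multi_rng.integers(len(others))]
                records[pos] = VariantRecord.build(
                    v.chrom, v.pos, v.ancestral, v.alleles + (extra,))

    if params.cluster_rate > 0:
        cl_rng = spawn_rng(params.seed, _CLUSTER)
        n_pairs = cl_rng.poisson(params.cluster_rate * L / 1000.0)
        for _ in range(n_pairs):
            a = int(cl_rng.integers(h + 4, L - h - 4))
            off = int(cl_rng.integers(1, 5)) * (1 if cl_rng.random() < 0.5 else -1)
            for pos in (a, a + off):
                if pos in records:
                    continue
                anc = BASES[codes[pos]]
                der = BASES[(codes[pos] + 1 + cl_rng.integers(3)) % 4]
                records[pos] = VariantRecord.build(params.chrom, pos, anc, (anc, der))

    variants = [records[p] for p in sorted(records)]

    spec = params.gene_annotation_spec or ((0, L, "+", "intronic"),)
    mask = RegionMask(pd.DataFrame(
        [(params.chrom, s, e, cls, strand) for s, e, strand, cls in spec],
        columns=["chrom", "start", "end", "cls", "strand"]))

    weights = np.bincount(site_kmers[valid], minlength=4 ** k).astype(float)
    weights /= weights.sum()
    truth = TruthContextTable(k, table, weights, params.base_frequencies)
    genome = {params.chrom: seq}
    return genome, mask, variants, truth
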