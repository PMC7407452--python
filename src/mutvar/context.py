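"""Variance in SNV density attributable to k-mer sequence context.

The statistic is the context-weighted variance

    sigma2_k = sum_c p_c (m_c - mbar)^2,   mbar = sum_c p_c m_c

where p_c is the (exactly counted) proportion of sites whose k-mer context
is c and m_c is the SNV density of context c. Each (context, direction)
cell is modelled as a binomial with a Beta(1,1) prior, giving a
Beta(1+s, 1+n-s) posterior per cell; posterior draws of the weighted
variance are formed by drawing every cell's rate independently and applying
the formula per draw. Cells with zero variants carry a Beta(1,1) posterior
— the uniform on [0,1] — which inflates the variance, so their prevalence
is tracked and warned about.

Per-cell random streams are counter-based (keyed on the cell's integer
code), so draws for one cell never depend on which other cells are present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._util import (BASE_TO_CODE, BASES, COMPLEMENT_CODE, cell_rng,
                    kmer_codes, revcomp_direction, seq_to_codes,
                    string_to_kmer)
from .genomic_io import RegionMask, VariantRecord

log = logging.getLogger(__name__)

#: warn when more than this fraction of valid cells has zero variants
EMPTY_CELL_WARN_FRACTION = 0.01

_CHUNK = 1024  # k-mers per streaming chunk when sampling variances


@dataclass
class ContextTable:
    """Per-(k-mer, direction) trial and success counts with context weights.

    ``trials[c]`` is the exact count of masked sites whose context is k-mer
    ``c`` (integer-coded); ``successes[c, t]`` the count of qualified SNVs
    in context ``c`` mutating the central base to base ``t``. The central
    base of each k-mer is the 'from' base of its three valid directions.
    """

    k: int
    trials: np.ndarray
    successes: np.ndarray
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or self.k < 1:
            raise ValueError("k must be odd and >= 1")
        n = 4 ** self.k
        if self.trials.shape != (n,) or self.successes.shape != (n, 4):
            raise ValueError("count array shapes inconsistent with k")
        if (self.successes.sum(axis=1) > self.trials).any():
            raise ValueError("successes exceed trials")

    @property
    def h(self) -> int:
        return (self.k - 1) // 2

    @property
    def central_base(self) -> np.ndarray:
        return (np.arange(4 ** self.k) // 4 ** self.h) % 4

    @property
    def weights(self) -> np.ndarray:
        """p_c: proportion of counted sites matching each context."""
        total = self.trials.sum()
        if total == 0:
            raise ValueError("context table has zero trials")
        return self.trials / total

    def weights_central(self, base: str) -> np.ndarray:
        """p_c(a): weights over contexts with central base a (others zero)."""
        sel = self.central_base == BASE_TO_CODE[base]
        total = self.trials[sel].sum()
        if total == 0:
            raise ValueError(f"no counted sites with central base {base}")
        w = np.zeros_like(self.trials, dtype=float)
        w[sel] = self.trials[sel] / total
        return w

    @property
    def empty_cell_fraction(self) -> float:
        """Fraction of valid (context, direction) cells with zero variants."""
        central = self.central_base
        valid = np.ones((4 ** self.k, 4), dtype=bool)
        valid[np.arange(4 ** self.k), central] = False
        return float((self.successes[valid] == 0).mean())

    def cell(self, kmer: str, direction: tuple[str, str]) -> tuple[int, int]:
        """(trials, successes) of one cell, by k-mer string and direction."""
        code = string_to_kmer(kmer)
        if kmer[self.h] != direction[0]:
            raise ValueError("direction 'from' base must be the central base")
        return int(self.trials[code]), int(self.successes[code, BASE_TO_CODE[direction[1]]])


def table_from_rates(probs: np.ndarray, weights: np.ndarray, k: int,
                     total_trials: float = 1e9) -> ContextTable:
    """Infinite-data-limit table: counts proportional to given probabilities.

    Used to feed ground-truth rate tables through the posterior machinery;
    with ``total_trials`` large the beta posteriors concentrate on the
    probabilities themselves.
    """
    trials = np.round(weights / max(weights.max(), 1e-300) * total_trials).astype(np.int64)
    successes = np.round(probs * trials[:, None]).astype(np.int64)
    central = (np.arange(4 ** k) // 4 ** ((k - 1) // 2)) % 4
    successes[np.arange(4 ** k), central] = 0
    return ContextTable(k, trials, successes)


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def count_contexts(genome: dict[str, str], mask: RegionMask, k: int) -> np.ndarray:
    """Exact k-mer counts centered on every maskable site.

    Sites within (k-1)/2 of an interval edge, or whose window contains an N,
    are skipped. Minus-strand intervals are counted on the reverse
    complement, orienting contexts with respect to the annotated strand.
    """
    if k % 2 == 0 or k < 1:
        raise ValueError("k must be odd and >= 1")
    counts = np.zeros(4 ** k, dtype=np.int64)
    for row in mask.intervals.itertuples(index=False):
        codes = seq_to_codes(genome[row.chrom][row.start : row.end])
        if row.strand == "-":
            codes = COMPLEMENT_CODE[codes][::-1]
        kc, valid = kmer_codes(codes, k)
        if len(kc):
            counts += np.bincount(kc[valid], minlength=4 ** k)
    return counts


def tally_cells(variants: list[VariantRecord], genome: dict[str, str],
                mask: RegionMask, k: int,
                mismatch_error_fraction: float = 0.01) -> ContextTable:
    """Fill trial and success counts for every (context, direction) cell.

    ``variants`` must already be qualified (and strand-oriented) against the
    same mask. Each variant increments the success count of its oriented
    context and direction; trials come from :func:`count_contexts`. Variants
    whose oriented ancestral base disagrees with the genome base at their
    position are counted as mismatches; more than ``mismatch_error_fraction``
    of them is an error.
    """
    h = (k - 1) // 2
    trials = count_contexts(genome, mask, k)
    successes = np.zeros((4 ** k, 4), dtype=np.int64)
    mismatches = 0
    tallied = 0

    seqs = {c: seq_to_codes(s) for c, s in genome.items()}
    iv_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in mask.intervals.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        iv_by_chrom[chrom] = (grp["start"].to_numpy(), grp["end"].to_numpy(),
                              grp["strand"].to_numpy())

    for v in variants:
        if v.direction is None:
            continue
        if v.chrom not in iv_by_chrom:
            continue
        starts, ends, strands = iv_by_chrom[v.chrom]
        i = np.searchsorted(starts, v.pos, side="right") - 1
        if i < 0 or v.pos >= ends[i]:
            continue
        if v.pos - h < starts[i] or v.pos + h >= ends[i]:
            continue  # context extends past the interval edge: not a counted site
        window = seqs[v.chrom][v.pos - h : v.pos + h + 1]
        if (window == 4).any():
            continue
        direction = v.direction
        if strands[i] == "-":
            window = COMPLEMENT_CODE[window][::-1]
            if v.strand == "+":  # not yet oriented by qualification
                direction = revcomp_direction(direction)
        if BASES[window[h]] != direction[0]:
            mismatches += 1
            continue
        code = 0
        for b in window:
            code = code * 4 + int(b)
        successes[code, BASE_TO_CODE[direction[1]]] += 1
        tallied += 1

    if tallied + mismatches > 0:
        frac = mismatches / (tallied + mismatches)
        if frac > mismatch_error_fraction:
            raise ValueError(
                f"{mismatches} of {tallied + mismatches} variants mismatch the "
                f"genome ancestral base ({100 * frac:.1f}%)")
    table = ContextTable(k, trials, successes, mismatches=mismatches)
    if table.trials.sum() and table.empty_cell_fraction > EMPTY_CELL_WARN_FRACTION:
        log.warning("%.1f%% of (context, direction) cells have zero variants; "
                    "their Beta(1,1) posteriors inflate the variance",
                    100 * table.empty_cell_fraction)
    return table


# ---------------------------------------------------------------------------
# posterior sampling
# ---------------------------------------------------------------------------

def sample_posteriors(table: ContextTable, n_draws: int, seed: int) -> np.ndarray:
    """Per-cell beta posterior draws, shape (4**k, 4, n_draws).

    Cell (c, t) with s successes of n trials is Beta(1+s, 1+n-s); cells on
    the diagonal (to-base equal to central base) are left at zero. Intended
    for small k; the variance statistics below sample in streams instead.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    n = 4 ** table.k
    central = table.central_base
    out = np.zeros((n, 4, n_draws))
    for c in range(n):
        for t in range(4):
            if t == central[c]:
                continue
            rng = cell_rng(seed, c * 4 + t)
            s = table.successes[c, t]
            out[c, t] = rng.beta(1 + s, 1 + table.trials[c] - s, n_draws)
    return out


def _cell_draws(trials: np.ndarray, successes: np.ndarray, keys: np.ndarray,
                n_draws: int, seed: int) -> np.ndarray:
    """Beta draws for a batch of cells: shape (len(keys), n_draws)."""
    out = np.empty((len(keys), n_draws))
    for i, key in enumerate(keys):
        rng = cell_rng(seed, int(key))
        out[i] = rng.beta(1 + successes[i], 1 + trials[i] - successes[i], n_draws)
    return out


@dataclass
class VariancePosterior:
    """Posterior draws of a weighted context-variance statistic."""

    draws: np.ndarray
    statistic_kind: str
    k: int
    direction: tuple[str, str] | None = None

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.draws, q))

    def credible_interval(self, level: float = 95.0) -> tuple[float, float]:
        half = (100.0 - level) / 2.0
        return self.percentile(half), self.percentile(100.0 - half)


def _weighted_variance_stream(table: ContextTable, weights: np.ndarray,
                              n_draws: int, seed: int,
                              direction: tuple[str, str] | None = None,
                              subset: np.ndarray | None = None):
    """Accumulate per-draw weighted mean/variance over cells in chunks.

    Per k-mer the rate is the sum of its per-direction cell draws (or the
    single direction's draw when ``direction`` is given). Returns
    (m_draws, var_draws, subset_contribution_draws or None).
    """
    n = 4 ** table.k
    central = table.central_base
    A = np.zeros(n_draws)   # sum p_c m_c
    B = np.zeros(n_draws)   # sum p_c m_c^2
    As = np.zeros(n_draws) if subset is not None else None
    Bs = np.zeros(n_draws) if subset is not None else None
    Ws = 0.0
    active = np.flatnonzero(weights > 0)
    for lo in range(0, len(active), _CHUNK):
        idx = active[lo : lo + _CHUNK]
        rates = np.zeros((len(idx), n_draws))
        for t in range(4):
            if direction is not None and t != BASE_TO_CODE[direction[1]]:
                continue
            sel = central[idx] != t
            if direction is not None:
                sel &= central[idx] == BASE_TO_CODE[direction[0]]
            rows = idx[sel]
            if not len(rows):
                continue
            rates[sel] += _cell_draws(table.trials[rows], table.successes[rows, t],
                                      rows * 4 + t, n_draws, seed)
        w = weights[idx][:, None]
        A += (w * rates).sum(axis=0)
        B += (w * rates ** 2).sum(axis=0)
        if subset is not None:
            smask = subset[idx]
            if smask.any():
                ws = weights[idx][smask][:, None]
                As += (ws * rates[smask]).sum(axis=0)
                Bs += (ws * rates[smask] ** 2).sum(axis=0)
                Ws += float(weights[idx][smask].sum())
    var = np.maximum(B - A ** 2, 0.0)
    contrib = None
    if subset is not None:
        # sum_{c in S} p_c (m_c - mbar)^2 = B_S - 2 mbar A_S + mbar^2 W_S
        contrib = np.maximum(Bs - 2 * A * As + A ** 2 * Ws, 0.0)
    return A, var, contrib


def variance_total(table: ContextTable, n_draws: int = 10_000,
                   seed: int = 0) -> VariancePosterior:
    """Posterior of sigma2_k: total variance in SNV density due to k-mer context."""
    weights = table.weights
    if abs(weights.sum() - 1) > 1e-9:
        raise ValueError("context weights must sum to 1")
    _, var, _ = _weighted_variance_stream(table, weights, n_draws, seed)
    return VariancePosterior(var, "total", table.k)


def variance_by_direction(table: ContextTable, direction: tuple[str, str],
                          n_draws: int = 10_000, seed: int = 0,
                          mean_convention: str = "direction") -> VariancePosterior:
    """Posterior of sigma2_k(a->b): variance of one mutation direction's densities.

    Deviations are taken around the direction-specific weighted mean by
    default. The ``literal`` convention instead centers on mbar_a, the
    all-direction SNV probability of sites with central base a, which mixes
    the direction's spread with its offset from the total rate.
    """
    a, b = direction
    if a == b or a not in BASES or b not in BASES:
        raise ValueError(f"invalid direction {direction}")
    if mean_convention not in ("direction", "literal"):
        raise ValueError(f"unknown mean convention {mean_convention!r}")
    weights = table.weights_central(a)
    A_dir, var, _ = _weighted_variance_stream(table, weights, n_draws, seed,
                                              direction=direction)
    if mean_convention == "direction":
        return VariancePosterior(var, "direction", table.k, direction)
    # literal: recompute deviations around the all-direction center mbar_a
    A_all, _, _ = _weighted_variance_stream(table, weights, n_draws, seed)
    # sum w (m - c)^2 = var + (A_dir - c)^2 with c = mbar_a
    draws = var + (A_dir - A_all) ** 2
    return VariancePosterior(draws, "direction", table.k, direction)


def flank_bins(k: int) -> np.ndarray:
    """Map each k-mer code to its flanking (k-1)-mer code (central base removed)."""
    h = (k - 1) // 2
    codes = np.arange(4 ** k)
    right = codes % 4 ** h
    left = codes // 4 ** (h + 1)
    return left * 4 ** h + right


def variance_marginalised(table: ContextTable, n_draws: int = 10_000,
                          seed: int = 0) -> VariancePosterior:
    """Variance due to the flanking neighborhood alone.

    Counts are pooled over the four central bases into bins indexed by the
    flanking (k-1)-mer, isolating the influence of the flanks from that of
    the mutating base and its interaction with them.
    """
    if table.k < 3:
        raise ValueError("marginalisation requires k >= 3")
    bins = flank_bins(table.k)
    nb = 4 ** (table.k - 1)
    trials = np.bincount(bins, weights=table.trials, minlength=nb).astype(np.int64)
    successes = np.bincount(bins, weights=table.successes.sum(axis=1),
                            minlength=nb).astype(np.int64)
    total = trials.sum()
    if total == 0:
        raise ValueError("context table has zero trials")
    weights = trials / total
    key0 = 4 ** (table.k + 1)  # key space disjoint from per-cell keys
    A = np.zeros(n_draws)
    B = np.zeros(n_draws)
    active = np.flatnonzero(weights > 0)
    for lo in range(0, len(active), _CHUNK):
        idx = active[lo : lo + _CHUNK]
        rates = _cell_draws(trials[idx], successes[idx], key0 + idx, n_draws, seed)
        w = weights[idx][:, None]
        A += (w * rates).sum(axis=0)
        B += (w * rates ** 2).sum(axis=0)
    var = np.maximum(B - A ** 2, 0.0)
    return VariancePosterior(var, "marginalised", table.k)


def cpg_subset(k: int, orientation: str = "standard") -> np.ndarray:
    """Boolean mask over k-mer codes for the CpG-dinucleotide-defined subset.

    ``standard``: central C with 3' G, or central G with 5' C (the CpG
    dinucleotide as usually defined). ``mirrored``: central C with 5'
    G, or central G with 3' C.
    """
    if k < 3:
        raise ValueError("CpG conditioning requires k >= 3")
    h = (k - 1) // 2
    codes = np.arange(4 ** k)
    at = lambda j: (codes // 4 ** (k - 1 - j)) % 4
    C, G = BASE_TO_CODE["C"], BASE_TO_CODE["G"]
    if orientation == "standard":
        return ((at(h) == C) & (at(h + 1) == G)) | ((at(h) == G) & (at(h - 1) == C))
    if orientation == "mirrored":
        return ((at(h) == C) & (at(h - 1) == G)) | ((at(h) == G) & (at(h + 1) == C))
    raise ValueError(f"unknown CpG orientation {orientation!r}")


@dataclass
class CpGVariance:
    """CpG-conditioned slice of the total context variance."""

    contribution: VariancePosterior  # sum over CpG contexts of p_c (m_c - mbar)^2
    share: VariancePosterior         # contribution / sigma2_k, per draw
    subset_weight: float             # total p_c mass of the CpG contexts


def variance_cpg(table: ContextTable, n_draws: int = 10_000, seed: int = 0,
                 orientation: str = "standard") -> CpGVariance:
    """Contribution of CpG-context sites to sigma2_k, and its share of the total."""
    weights = table.weights
    subset = cpg_subset(table.k, orientation)
    _, var, contrib = _weighted_variance_stream(table, weights, n_draws, seed,
                                                subset=subset)
    share = np.where(var > 0, contrib / np.where(var > 0, var, 1.0), 0.0)
    return CpGVariance(
        contribution=VariancePosterior(contrib, "cpg", table.k),
        share=VariancePosterior(share, "cpg-share", table.k),
        subset_weight=float(weights[subset].sum()),
    )


# ---------------------------------------------------------------------------
# strand asymmetry
# ---------------------------------------------------------------------------

@dataclass
class StrandAsymmetryResult:
    asymmetric: bool
    directions: tuple[tuple[str, str] | None, tuple[str, str] | None]
    percentiles: dict  # {"a": (q2.5, q97.5), "b": (q2.5, q97.5)}


def strand_asymmetry(post_a: VariancePosterior, post_b: VariancePosterior,
                     lower: float = 2.5, upper: float = 97.5) -> StrandAsymmetryResult:
    """Percentile-separation test for a strand-complementary posterior pair.

    The pair is called asymmetric iff the upper percentile of one posterior
    lies below the lower percentile of the other (in either direction).
    """
    if post_a.k != post_b.k:
        raise ValueError("posteriors have different k")
    if post_a.statistic_kind != post_b.statistic_kind:
        raise ValueError("posteriors are different statistic kinds")
    qa = (post_a.percentile(lower), post_a.percentile(upper))
    qb = (post_b.percentile(lower), post_b.percentile(upper))
    asymmetric = qa[1] < qb[0] or qb[1] < qa[0]
    return StrandAsymmetryResult(asymmetric, (post_a.direction, post_b.direction),
                                 {"a": qa, "b": qb})


# ---------------------------------------------------------------------------
# exact (infinite-data) oracles over probability tables
# ---------------------------------------------------------------------------

def exact_weighted_variance(probs: np.ndarray, weights: np.ndarray) -> float:
    """sigma2_k evaluated directly on a (4**k, 4) probability table."""
    rates = probs.sum(axis=1)
    m = float(np.dot(weights, rates))
    return float(np.dot(weights, (rates - m) ** 2))


def exact_variance_by_direction(probs: np.ndarray, weights: np.ndarray, k: int,
                                direction: tuple[str, str],
                                mean_convention: str = "direction") -> float:
    central = (np.arange(4 ** k) // 4 ** ((k - 1) // 2)) % 4
    sel = central == BASE_TO_CODE[direction[0]]
    w = weights[sel] / weights[sel].sum()
    m = probs[sel, BASE_TO_CODE[direction[1]]]
    if mean_convention == "direction":
        center = float(np.dot(w, m))
    else:
        center = float(np.dot(w, probs[sel].sum(axis=1)))
    return float(np.dot(w, (m - center) ** 2))


def exact_variance_marginalised(probs: np.ndarray, weights: np.ndarray, k: int) -> float:
    bins = flank_bins(k)
    nb = 4 ** (k - 1)
    wb = np.bincount(bins, weights=weights, minlength=nb)
    mb = np.bincount(bins, weights=weights * probs.sum(axis=1), minlength=nb)
    nz = wb > 0
    rates = mb[nz] / wb[nz]
    m = float(np.dot(wb[nz], rates))
    return float(np.dot(wb[nz], (rates - m) ** 2))
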