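"""Data-qualification rules and analysis-ready structures.

Two consumers are served: the k-mer context analysis, which needs SNVs that
satisfy the independence assumptions of the per-site Bernoulli model
(biallelic, ancestral allele known, no other variant within 4 bp on either
side, strand-oriented within annotated regions); and the recombination
regression, which needs per-10-kb-block SNV densities on a contiguous lag
grid, with excluded blocks imputed by Last Observation Carried Forward so
that the ARMA lag structure is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._util import revcomp_direction, seq_to_codes
from .genomic_io import RecombinationMap, RegionMask, VariantRecord

log = logging.getLogger(__name__)

#: exclusion reasons for blocks
NO_SNV = "no-snv"
DECODE_MISSING = "decode-missing"
ADJACENT = "adjacent"

#: excluded fraction above which a warning is logged (the deCODE-based
#: analysis never exceeded 5% of a chromosome)
EXCLUDED_WARN_FRACTION = 0.05


@dataclass
class BlockSeries:
    """Aligned per-block recombination rates and SNV densities for one chromosome.

    ``rate`` and ``density`` are the analysis series (after any LOCF
    substitution); ``shadow_rate`` / ``shadow_density`` retain the observed
    pre-substitution values. ``rate_missing`` marks blocks the map flags as
    unsequenced ("deCODE missing"). ``exclude_reason`` is "" for retained
    blocks.
    """

    chrom: str
    start: np.ndarray
    rate: np.ndarray
    density: np.ndarray
    block_size: int = 10_000
    rate_missing: np.ndarray | None = None
    direction_density: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    excluded: np.ndarray | None = None
    exclude_reason: np.ndarray | None = None
    locf_applied: np.ndarray | None = None
    shadow_rate: np.ndarray | None = None
    shadow_density: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.rate)
        if len(self.density) != n or len(self.start) != n:
            raise ValueError("rate/density/start arrays must have equal length")
        if self.rate_missing is None:
            self.rate_missing = np.zeros(n, dtype=bool)
        if self.excluded is None:
            self.excluded = np.zeros(n, dtype=bool)
        if self.exclude_reason is None:
            self.exclude_reason = np.array([""] * n, dtype=object)
        if self.locf_applied is None:
            self.locf_applied = np.zeros(n, dtype=bool)
        dens = self.density[~self.rate_missing]
        if len(dens) and (np.nanmin(dens) < 0 or np.nanmax(dens) > 1):
            raise ValueError("density outside [0,1]")
        for d, arr in self.direction_density.items():
            if len(arr) != n:
                raise ValueError(f"direction density {d} length mismatch")

    def __len__(self) -> int:
        return len(self.rate)

    @property
    def mean_density_observed(self) -> float:
        """Mean SNV density over blocks with observed (non-imputed) data."""
        keep = ~self.locf_applied
        return float(np.mean(self.density[keep]))

    def for_direction(self, direction: tuple[str, str]) -> "BlockSeries":
        """View of the series with one direction's density as the analysis density."""
        if direction not in self.direction_density:
            raise KeyError(f"no density for direction {direction}")
        return BlockSeries(
            chrom=self.chrom,
            start=self.start,
            rate=self.rate,
            density=self.direction_density[direction],
            block_size=self.block_size,
            rate_missing=self.rate_missing,
            excluded=self.excluded,
            exclude_reason=self.exclude_reason,
            locf_applied=self.locf_applied,
            shadow_rate=self.shadow_rate,
        )


# ---------------------------------------------------------------------------
# context-analysis variant qualification
# ---------------------------------------------------------------------------

def qualify_context_variants(
    variants: list[VariantRecord],
    mask: RegionMask,
    neighborhood: int = 4,
    genome: dict[str, str] | None = None,
    min_separation: int | None = None,
) -> list[VariantRecord]:
    """Retain variants satisfying the per-site independence assumptions.

    A variant survives iff it is biallelic, its ancestral allele is one of
    its observed alleles, it lies inside a mask interval, and no other
    variant of any kind sits within ``neighborhood`` bp on either side
    (disqualifying distance ``<= neighborhood``; all variants act as
    disqualifiers, including ones that are themselves removed). For variants
    in minus-strand intervals the direction is reverse-complemented and the
    record's strand set to '-', so downstream context tallies are oriented
    with respect to the annotated gene strand.

    ``min_separation`` offers the alternative reading of the spacing rule
    (disqualify iff distance < min_separation); it overrides ``neighborhood``.
    """
    by_chrom: dict[str, list[VariantRecord]] = {}
    last_key: tuple[str, int] | None = None
    seen_chroms: set[str] = set()
    for v in variants:
        if last_key is not None and last_key[0] == v.chrom and v.pos < last_key[1]:
            raise ValueError("variants must be sorted by (chrom, pos)")
        if last_key is None or last_key[0] != v.chrom:
            if v.chrom in seen_chroms:
                raise ValueError("variants must be sorted by (chrom, pos)")
            seen_chroms.add(v.chrom)
        last_key = (v.chrom, v.pos)
        by_chrom.setdefault(v.chrom, []).append(v)

    out: list[VariantRecord] = []
    counts = {"input": len(variants), "non_biallelic": 0, "no_ancestral": 0,
              "outside_mask": 0, "neighbor": 0, "retained": 0}
    for chrom, vs in by_chrom.items():
        if genome is not None:
            if chrom not in genome:
                raise ValueError(f"variant chromosome {chrom!r} absent from genome")
            L = len(genome[chrom])
            if any(v.pos < 0 or v.pos >= L for v in vs):
                raise ValueError(f"variant outside genome bounds on {chrom}")
        pos = np.array([v.pos for v in vs])
        if len(pos) > 1:
            gap_prev = np.diff(pos, prepend=pos[0] - 10 * (neighborhood + 1))
            gap_next = np.diff(pos, append=pos[-1] + 10 * (neighborhood + 1))
            if min_separation is not None:
                crowded = (gap_prev < min_separation) | (gap_next < min_separation)
            else:
                crowded = (gap_prev <= neighborhood) | (gap_next <= neighborhood)
        else:
            crowded = np.zeros(len(pos), dtype=bool)

        iv = mask.intervals[mask.intervals["chrom"] == chrom]
        starts = iv["start"].to_numpy()
        ends = iv["end"].to_numpy()
        strands = iv["strand"].to_numpy()
        order = np.argsort(starts)
        starts, ends, strands = starts[order], ends[order], strands[order]
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])

        for j, v in enumerate(vs):
            if not v.biallelic:
                counts["non_biallelic"] += 1
                continue
            if v.direction is None:
                counts["no_ancestral"] += 1
                continue
            if not inside[j]:
                counts["outside_mask"] += 1
                continue
            if crowded[j]:
                counts["neighbor"] += 1
                continue
            strand = strands[idx[j]]
            if strand == "-" and v.strand == "+":
                direction = revcomp_direction(v.direction)
                v = VariantRecord(v.chrom, v.pos, direction[0],
                                  tuple(sorted(direction)), True, direction, "-")
            out.append(v)
            counts["retained"] += 1
    log.info("qualify_context_variants: %s", counts)
    return out


# ---------------------------------------------------------------------------
# block series assembly
# ---------------------------------------------------------------------------

def apply_exclusions(series: BlockSeries) -> BlockSeries:
    """Apply the three block-exclusion rules and LOCF imputation.

    Excluded are: blocks with no SNVs; blocks the map flags as missing
    ("deCODE missing"); and the single block on each side of a missing
    block. Every excluded block's rate, density and per-direction densities
    are replaced by those of its nearest non-excluded 5' neighbor, keeping
    the lag grid contiguous. Excluded blocks at the head of the series have
    no 5' neighbor and are dropped (count logged).
    """
    n = len(series)
    missing = series.rate_missing.copy()
    reason = np.array([""] * n, dtype=object)
    reason[series.density == 0] = NO_SNV
    adj = np.zeros(n, dtype=bool)
    adj[:-1] |= missing[1:]
    adj[1:] |= missing[:-1]
    reason[adj & ~missing] = ADJACENT
    reason[missing] = DECODE_MISSING
    excluded = reason != ""

    frac = float(excluded.mean()) if n else 0.0
    if frac > EXCLUDED_WARN_FRACTION:
        log.warning("excluded fraction %.1f%% exceeds %.0f%% on %s",
                    100 * frac, 100 * EXCLUDED_WARN_FRACTION, series.chrom)

    # drop head blocks with no 5' neighbor to carry forward
    head = 0
    while head < n and excluded[head]:
        head += 1
    if head:
        log.info("dropped %d head blocks with no 5' neighbor on %s", head, series.chrom)
    if head == n:
        raise ValueError("all blocks excluded")

    sl = slice(head, n)
    excluded = excluded[sl]
    reason = reason[sl]
    rate = series.rate[sl].astype(float).copy()
    density = series.density[sl].astype(float).copy()
    missing = missing[sl]
    dir_dens = {d: a[sl].astype(float).copy() for d, a in series.direction_density.items()}
    shadow_rate = rate.copy()
    shadow_density = density.copy()

    # LOCF: index of nearest non-excluded 5' block
    idx = np.arange(len(rate))
    src = np.where(excluded, -1, idx)
    src = np.maximum.accumulate(src)
    locf = excluded.copy()
    rate[locf] = rate[src[locf]]
    density[locf] = density[src[locf]]
    for arr in dir_dens.values():
        arr[locf] = arr[src[locf]]

    return BlockSeries(
        chrom=series.chrom,
        start=series.start[sl].copy(),
        rate=rate,
        density=density,
        block_size=series.block_size,
        rate_missing=missing,
        direction_density=dir_dens,
        excluded=excluded,
        exclude_reason=reason,
        locf_applied=locf,
        shadow_rate=shadow_rate,
        shadow_density=shadow_density,
    )


def build_block_series(
    variants: list[VariantRecord],
    rmap: RecombinationMap,
    genome: dict[str, str] | None = None,
    chrom: str | None = None,
) -> BlockSeries:
    """Count SNVs per map block, derive densities, and apply exclusions + LOCF.

    Per-direction densities use the count of ancestral-base sites in the
    block as denominator (so a block with 100 C sites and 5 C->T SNVs has
    direction density 0.05); they require ``genome``. Total density uses all
    variants, including ones whose ancestral state is unknown.
    """
    chroms = rmap.blocks["chrom"].unique()
    if chrom is None:
        if len(chroms) != 1:
            raise ValueError("multi-chromosome map: pass chrom explicitly")
        chrom = chroms[0]
    rmap = rmap.for_chrom(chrom)
    blocks = rmap.blocks
    starts = blocks["start"].to_numpy()
    ends = blocks["end"].to_numpy()

    vs = sorted((v for v in variants if v.chrom == chrom), key=lambda v: v.pos)
    pos = np.array([v.pos for v in vs], dtype=np.int64)
    counts = np.searchsorted(pos, ends) - np.searchsorted(pos, starts)
    density = counts / rmap.block_size

    dir_dens: dict[tuple[str, str], np.ndarray] = {}
    if genome is not None:
        codes = seq_to_codes(genome[chrom])
        base_counts = np.zeros((len(starts), 4), dtype=np.int64)
        cum = np.zeros((len(codes) + 1, 4), dtype=np.int64)
        for b in range(4):
            cum[1:, b] = np.cumsum(codes == b)
        lo = np.clip(starts, 0, len(codes))
        hi = np.clip(ends, 0, len(codes))
        base_counts = cum[hi] - cum[lo]

        from ._util import BASE_TO_CODE, DIRECTIONS
        for d in DIRECTIONS:
            dpos = np.array([v.pos for v in vs if v.direction == d], dtype=np.int64)
            dcount = np.searchsorted(dpos, ends) - np.searchsorted(dpos, starts)
            denom = base_counts[:, BASE_TO_CODE[d[0]]].astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                dd = np.where(denom > 0, dcount / np.where(denom > 0, denom, 1), 0.0)
            dir_dens[d] = dd

    raw = BlockSeries(
        chrom=chrom,
        start=starts.copy(),
        rate=blocks["rate"].to_numpy(dtype=float),
        density=density,
        block_size=rmap.block_size,
        rate_missing=blocks["missing"].to_numpy(dtype=bool),
        direction_density=dir_dens,
    )
    return apply_exclusions(raw)


def chromosome_rate_variance(rmap: RecombinationMap,
                             genome_mean_rate: float | None = None) -> float:
    """Variance of block recombination rates normalized by the genome mean.

    ``genome_mean_rate`` defaults to the mean over all non-missing blocks of
    the map passed in; pass the whole-genome mean when computing per
    chromosome. Population variance (ddof=0).
    """
    rates = rmap.blocks.loc[~rmap.blocks["missing"], "rate"].to_numpy(dtype=float)
    if len(rates) < 2:
        raise ValueError("need at least 2 non-missing blocks")
    mean = genome_mean_rate if genome_mean_rate is not None else float(rates.mean())
    if mean == 0:
        raise ValueError("zero mean recombination rate")
    return float(np.var(rates / mean, ddof=0))
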