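"""Readers and writers for the four external file kinds.

All coordinates are 0-based half-open internally; 1-based coordinates occur
only at the VCF boundary. Recombination maps follow a configurable
tab-delimited dialect (the deCODE addendum files do not ship with a printed
schema, so column order, header presence and the missing-data marker are all
declared through :class:`RmapDialect`).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

log = logging.getLogger(__name__)

VALID_BASES = {"A", "C", "G", "T"}


class ParseError(ValueError):
    """Malformed input row; message names the offending line."""


class ValidationError(ValueError):
    """Structurally parseable input violating an invariant."""


# ---------------------------------------------------------------------------
# recombination map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RmapDialect:
    """Column layout of a tab/whitespace-delimited recombination-rate file."""

    columns: tuple[str, ...] = ("chrom", "start", "rate")
    header: bool = False
    missing_marker: str = "NA"
    block_size: int = 10_000


@dataclass
class RecombinationMap:
    """Per-block standardized recombination rates for one or more chromosomes.

    ``blocks`` has columns chrom, start, end, rate (NaN where missing),
    missing (bool). ``mean_cM_per_block`` is the genetic-map calibration
    constant: the genome-wide average genetic distance per block (0.0116 cM
    for the deCODE 10-kb map), used to convert slopes from per-standardized-
    rate-unit to per-centimorgan.
    """

    blocks: pd.DataFrame
    block_size: int = 10_000
    mean_cM_per_block: float = 0.0116

    def __post_init__(self) -> None:
        b = self.blocks
        required = {"chrom", "start", "end", "rate", "missing"}
        if not required.issubset(b.columns):
            raise ValidationError(f"block table missing columns {required - set(b.columns)}")
        for chrom, grp in b.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(np.diff(starts) <= 0):
                raise ValidationError(f"blocks not sorted by start on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"overlapping blocks on {chrom}")
            if np.any(ends - starts != self.block_size):
                raise ValidationError(
                    f"block length != configured block size {self.block_size} on {chrom}"
                )
        rates = b.loc[~b["missing"], "rate"]
        if (rates < 0).any():
            raise ValidationError("negative recombination rate")

    def __len__(self) -> int:
        return len(self.blocks)

    def for_chrom(self, chrom: str) -> "RecombinationMap":
        sub = self.blocks[self.blocks["chrom"] == chrom].reset_index(drop=True)
        return RecombinationMap(sub, self.block_size, self.mean_cM_per_block)


def read_recomb_map(path: str | Path, dialect: RmapDialect = RmapDialect()) -> RecombinationMap:
    """Read a recombination map in the configured dialect.

    Rows whose rate equals the dialect's missing marker are retained with a
    missing flag: the downstream exclusion/LOCF logic needs to see them.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if dialect.header and lineno == 1:
                continue
            parts = line.split()
            if len(parts) < len(dialect.columns):
                raise ParseError(f"{path}: line {lineno}: expected "
                                 f"{len(dialect.columns)} columns, got {len(parts)}")
            rec = dict(zip(dialect.columns, parts))
            try:
                start = int(rec["start"])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad start {rec['start']!r}") from exc
            raw_rate = rec["rate"]
            if raw_rate == dialect.missing_marker:
                rate, missing = np.nan, True
            else:
                try:
                    rate = float(raw_rate)
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: bad rate {raw_rate!r}") from exc
                missing = False
            end = int(rec["end"]) if "end" in rec else start + dialect.block_size
            rows.append((rec["chrom"], start, end, rate, missing))
    blocks = pd.DataFrame(rows, columns=["chrom", "start", "end", "rate", "missing"])
    return RecombinationMap(blocks, block_size=dialect.block_size)


def write_recomb_map(rmap: RecombinationMap, path: str | Path,
                     dialect: RmapDialect = RmapDialect()) -> None:
    with open(path, "w") as fh:
        for row in rmap.blocks.itertuples(index=False):
            rate = dialect.missing_marker if row.missing else repr(float(row.rate))
            rec = {"chrom": row.chrom, "start": row.start, "end": row.end, "rate": rate}
            fh.write("\t".join(str(rec[c]) for c in dialect.columns) + "\n")


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """One observed SNV with its inferred mutation direction.

    ``pos`` is 0-based. ``direction`` is the ordered (ancestral, derived)
    pair, defined only for biallelic records whose ancestral allele is one of
    the observed alleles. ``strand`` records the orientation applied by the
    qualification step ('+' until then).
    """

    chrom: str
    pos: int
    ancestral: str | None
    alleles: tuple[str, ...]
    biallelic: bool
    direction: tuple[str, str] | None
    strand: str = "+"

    @staticmethod
    def build(chrom: str, pos: int, ancestral: str | None,
              alleles: tuple[str, ...]) -> "VariantRecord":
        alleles = tuple(sorted({a.upper() for a in alleles}))
        ancestral = ancestral.upper() if ancestral else None
        if ancestral not in VALID_BASES:
            ancestral = None
        biallelic = len(alleles) == 2
        direction = None
        if biallelic and ancestral in alleles:
            derived = alleles[0] if alleles[1] == ancestral else alleles[1]
            direction = (ancestral, derived)
        return VariantRecord(chrom, pos, ancestral, alleles, biallelic, direction)


def read_variants(path: str | Path, format: str = "vcf") -> list[VariantRecord]:
    """Read variants from VCF (AA info key) or TSV (chrom, pos1, ancestral, alleles).

    VCF positions are converted from 1-based to 0-based. Records with allele
    characters outside {A,C,G,T,N} (indels, symbolic alleles) are skipped and
    counted in a logged warning.
    """
    records: list[VariantRecord] = []
    skipped = 0
    if format == "vcf":
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                alleles = tuple(a.upper() for a in rec.alleles)
                if any(len(a) != 1 or a not in VALID_BASES | {"N"} for a in alleles):
                    skipped += 1
                    continue
                aa = rec.info.get("AA")
                if isinstance(aa, tuple):
                    aa = aa[0]
                records.append(VariantRecord.build(rec.chrom, rec.pos - 1, aa, alleles))
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for row in df.itertuples(index=False):
            alleles = tuple(row.alleles.upper().split(","))
            if any(len(a) != 1 or a not in VALID_BASES | {"N"} for a in alleles):
                skipped += 1
                continue
            aa = None if row.ancestral in (".", "", None) else row.ancestral
            records.append(VariantRecord.build(row.chrom, int(row.pos) - 1, aa, alleles))
    else:
        raise ValueError(f"unknown variant format {format!r}")
    if skipped:
        log.warning("skipped %d variant records with non-SNV alleles", skipped)
    return records


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variants_vcf(variants: list[VariantRecord], path: str | Path,
                       contig_lengths: dict[str, int] | None = None) -> None:
    """Write SNVs as uncompressed VCF with the AA info key filled.

    The record REF is the ancestral allele when known (the synthetic genome
    is the ancestral sequence), otherwise the alphabetically first allele.
    """
    contig_lengths = contig_lengths or {}
    contigs = "".join(f"##contig=<ID={c},length={n}>\n" for c, n in contig_lengths.items())
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs))
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            ref = v.ancestral if v.ancestral in v.alleles else v.alleles[0]
            alts = [a for a in v.alleles if a != ref]
            aa = v.ancestral or "."
            fh.write(f"{v.chrom}\t{v.pos + 1}\t.\t{ref}\t{','.join(alts)}\t.\t.\tAA={aa}\n")


# ---------------------------------------------------------------------------
# region masks
# ---------------------------------------------------------------------------

@dataclass
class RegionMask:
    """Half-open genomic intervals with strand and functional class.

    ``intervals`` has columns chrom, start, end, cls, strand. Overlapping
    intervals of the same (chrom, class, strand) are merged on construction
    via :func:`read_regions`.
    """

    intervals: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "cls", "strand"]))

    def __post_init__(self) -> None:
        iv = self.intervals
        if len(iv) and (iv["start"] >= iv["end"]).any():
            raise ValidationError("interval with start >= end")

    def __len__(self) -> int:
        return len(self.intervals)

    def select(self, cls: str | None = None, chrom: str | None = None) -> "RegionMask":
        iv = self.intervals
        if cls is not None:
            iv = iv[iv["cls"] == cls]
        if chrom is not None:
            iv = iv[iv["chrom"] == chrom]
        return RegionMask(iv.reset_index(drop=True))

    def contains(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: which of the sorted positions fall in any interval."""
        out = np.zeros(len(pos), dtype=bool)
        iv = self.intervals[self.intervals["chrom"] == chrom]
        for row in iv.itertuples(index=False):
            out |= (pos >= row.start) & (pos < row.end)
        return out


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    merged_rows = []
    for (chrom, cls, strand), grp in df.groupby(["chrom", "cls", "strand"], sort=False):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        for row in grp.itertuples(index=False):
            if cur_start is None:
                cur_start, cur_end = row.start, row.end
            elif row.start <= cur_end:
                cur_end = max(cur_end, row.end)
            else:
                merged_rows.append((chrom, cur_start, cur_end, cls, strand))
                cur_start, cur_end = row.start, row.end
        if cur_start is not None:
            merged_rows.append((chrom, cur_start, cur_end, cls, strand))
    out = pd.DataFrame(merged_rows, columns=["chrom", "start", "end", "cls", "strand"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def read_regions(path: str | Path) -> RegionMask:
    """Read a BED6-style mask (chrom, start, end, class, score, strand)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 BED columns")
            chrom, start, end, cls, _score, strand = parts[:6]
            start, end = int(start), int(end)
            if start >= end:
                raise ValidationError(f"{path}: line {lineno}: start >= end")
            rows.append((chrom, start, end, cls, strand))
    if not rows:
        return RegionMask()
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "cls", "strand"])
    return RegionMask(_merge_intervals(df))


def write_regions(mask: RegionMask, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in mask.intervals.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.cls}\t0\t{row.strand}\n")


# ---------------------------------------------------------------------------
# genome sequence & result tables
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA genome into memory, uppercased. N bases are preserved."""
    with Fasta(str(path)) as fa:
        return {name: str(rec[:]).upper() for name, rec in fa.items()}


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Tab-delimited result table (Table-1-style and friends)."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
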