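"""Genomic coordinate primitives: intervals, interval sets, BED I/O, genome bins.

Internal convention is 0-based half-open throughout, as in BED. Inputs printed
1-based inclusive (locus tables, proxy tables) are converted at parse time via
the ``table1`` coordinate dialect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = {"+", "-", None}


class BedParseError(ValueError):
    """Raised for malformed BED-family records; carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open span [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+', '-' or None, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Any-overlap (>= 1 bp) under half-open semantics."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.name)

    def __str__(self) -> str:  # chr22:24234492-24237862 style (half-open)
        return f"{self.chrom}:{self.start}-{self.end}"


class IntervalSet:
    """A normalized (sorted, deduplicated) collection of GenomicInterval."""

    def __init__(self, intervals: Iterable[GenomicInterval] = (), normalize: bool = True):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.sorted_flag = False
        self.n_duplicates_dropped = 0
        if normalize:
            self.normalize()

    def normalize(self) -> "IntervalSet":
        """Sort by (chrom, start, end) and drop duplicate (chrom,start,end,name) records."""
        seen: set[tuple] = set()
        unique = []
        for iv in self.intervals:
            k = iv.key()
            if k in seen:
                self.n_duplicates_dropped += 1
                continue
            seen.add(k)
            unique.append(iv)
        if self.n_duplicates_dropped:
            logger.info("dropped %d duplicate interval records", self.n_duplicates_dropped)
        unique.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
        self.intervals = unique
        self.sorted_flag = True
        return self

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def chromosomes(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees for overlap queries."""
        by_chrom: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        return by_chrom


def _check_chrom_overlap(query: IntervalSet, subject: IntervalSet) -> None:
    qc, sc = query.chromosomes(), subject.chromosomes()
    if qc and sc and not (qc & sc):
        warnings.warn(
            "query and subject share no chromosome names; "
            f"query-only={sorted(qc - sc)}, subject-only={sorted(sc - qc)}",
            stacklevel=3,
        )


def intersect_any(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Per-query boolean: does the query interval share >= 1 bp with any subject interval?

    bedtools-intersect ``-u`` semantics on half-open coordinates.
    """
    _check_chrom_overlap(query, subject)
    trees = subject.trees()
    flags = np.zeros(len(query), dtype=bool)
    for i, iv in enumerate(query):
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            flags[i] = True
    return flags


@dataclass
class GenomeBins:
    """Fixed-width tiling of a genome; the counting unit for enrichment tests.

    Bins are laid out chromosome by chromosome in the insertion order of
    ``chrom_sizes``; the final bin of each chromosome may be short.
    """

    chrom_sizes: dict[str, int]
    bin_size: int = 100
    _offsets: dict[str, int] = field(init=False, repr=False)
    n_bins: int = field(init=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be > 0, got {self.bin_size}")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive size {size}")
        self._offsets = {}
        total = 0
        for chrom, size in self.chrom_sizes.items():
            self._offsets[chrom] = total
            total += -(-size // self.bin_size)  # ceil division
        self.n_bins = total

    def n_bins_for(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.bin_size)

    def iter_bins(self) -> Iterator[GenomicInterval]:
        for chrom, size in self.chrom_sizes.items():
            for start in range(0, size, self.bin_size):
                yield GenomicInterval(chrom, start, min(start + self.bin_size, size))

    def overlap_flags(self, intervals: IntervalSet | Sequence[GenomicInterval]) -> np.ndarray:
        """Boolean vector over all bins: bin shares >= 1 bp with some interval.

        Exact for a fixed grid: interval [s, e) touches bins floor(s/w) .. ceil(e/w)-1.
        """
        flags = np.zeros(self.n_bins, dtype=bool)
        w = self.bin_size
        for iv in intervals:
            if iv.chrom not in self._offsets:
                continue
            off = self._offsets[iv.chrom]
            n = self.n_bins_for(iv.chrom)
            lo = min(iv.start // w, n)
            hi = min(-(-iv.end // w), n)
            if hi > lo:
                flags[off + lo : off + hi] = True
        return flags

    def bin_interval(self, index: int) -> GenomicInterval:
        """The genomic span of the bin with a given global index."""
        for chrom in self.chrom_sizes:
            off = self._offsets[chrom]
            n = self.n_bins_for(chrom)
            if off <= index < off + n:
                start = (index - off) * self.bin_size
                return GenomicInterval(
                    chrom, start, min(start + self.bin_size, self.chrom_sizes[chrom])
                )
        raise IndexError(index)


def make_bins(chrom_sizes: dict[str, int], bin_size: int = 100) -> GenomeBins:
    """Tile each chromosome into fixed-width bins (default 100 bp)."""
    return GenomeBins(dict(chrom_sizes), bin_size)


def _parse_bed_line(
    fields: list[str], lineno: int, dialect: str
) -> GenomicInterval:
    if len(fields) < 3:
        raise BedParseError(f"line {lineno}: expected >= 3 tab-separated columns")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
    if dialect == "table1":
        # 1-based inclusive -> 0-based half-open
        if start < 1:
            raise BedParseError(
                f"line {lineno}: 1-based inclusive coordinates cannot start at {start}"
            )
        start -= 1
    elif dialect != "bed0":
        raise ValueError(f"unknown coordinate dialect {dialect!r}")
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else None
    if end <= start:
        raise BedParseError(
            f"line {lineno}: end {end} <= start {start} after dialect conversion"
        )
    return GenomicInterval(chrom, start, end, name=name, strand=strand)


def read_bed(path: str | Path, coordinate_dialect: str = "bed0") -> IntervalSet:
    """Read a BED3/4/6 file into a normalized IntervalSet.

    ``coordinate_dialect='table1'`` declares the file 1-based inclusive (locus-table
    style) and shifts starts by -1 on parse.
    """
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            intervals.append(_parse_bed_line(line.split("\t"), lineno, coordinate_dialect))
    return IntervalSet(intervals)


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED (3, 4 or 6 columns depending on name/strand presence)."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.strand is not None:
                cols += ["0", iv.strand]
            fh.write("\t".join(cols) + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column chromosome-sizes file (name, length in bp)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise BedParseError(f"line {lineno}: expected two columns (name, length)")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
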