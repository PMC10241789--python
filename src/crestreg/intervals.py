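"""Genomic interval primitives shared by every pipeline stage.

All coordinates are 0-based half-open throughout the package (the BED
convention).  Coordinates quoted 1-based (e.g. from genome-browser text such
as ``chr6:50,913,170-51,087,888``) are converted on ingestion by subtracting
one from the start.  Chromosome names are compared by exact string equality;
no ``chr`` prefix normalization is performed.  Strand is carried but ignored
by all overlap operations.
"""

from __future__ import annotations

import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of +, -, ., got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def distance(self, other: "GenomicInterval") -> int | None:
        """Gap in bp between two intervals; 0 if overlapping, None if
        on different chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def from_one_based(chrom: str, start: int, end: int, strand: str = ".") -> GenomicInterval:
    """Build an interval from 1-based inclusive coordinates (browser style)."""
    return GenomicInterval(chrom, start - 1, end, strand)


_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


def parse_region(text: str) -> GenomicInterval:
    """Parse a ``chrom:start-end`` region string (0-based half-open).

    Commas in coordinates are ignored.
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end")
    chrom = m.group(1)
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    return GenomicInterval(chrom, start, end)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with a single TSS (width-1 interval) and a length for RPKM."""

    gene_id: str
    tss: GenomicInterval
    gene_length_bp: int

    def __post_init__(self) -> None:
        if self.tss.width != 1:
            raise ValueError("tss must be a width-1 interval")
        if self.gene_length_bp <= 0:
            raise ValueError("gene_length_bp must be > 0")

    @property
    def chrom(self) -> str:
        return self.tss.chrom

    @property
    def tss_pos(self) -> int:
        return self.tss.start


class IntervalIndex:
    """Overlap queries against a fixed interval collection.

    Per chromosome, interval starts are kept sorted together with a running
    maximum of ends, so a query costs O(log n + hits).  Sufficient for the
    peak/fragment scales this pipeline works at.
    """

    def __init__(self, intervals: list[GenomicInterval]):
        self._by_chrom: dict[str, tuple[list[int], list[int], list[int]]] = {}
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for i, iv in enumerate(intervals):
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
        for chrom, triples in per_chrom.items():
            triples.sort()
            starts = [t[0] for t in triples]
            ends = [t[1] for t in triples]
            idx = [t[2] for t in triples]
            self._by_chrom[chrom] = (starts, ends, idx)
        self.intervals = list(intervals)

    def overlapping(self, query: GenomicInterval) -> list[int]:
        """Indices (into the original list) of intervals overlapping query."""
        entry = self._by_chrom.get(query.chrom)
        if entry is None:
            return []
        starts, ends, idx = entry
        # candidates start before query.end; filter on end > query.start
        hi = bisect_left(starts, query.end)
        return [idx[j] for j in range(hi) if ends[j] > query.start]

    def any_overlap(self, query: GenomicInterval) -> bool:
        entry = self._by_chrom.get(query.chrom)
        if entry is None:
            return False
        starts, ends, _ = entry
        hi = bisect_left(starts, query.end)
        return any(ends[j] > query.start for j in range(hi))


@dataclass
class TssIndex:
    """Nearest-TSS lookup per chromosome."""

    annotation: list[GeneAnnotation]
    _positions: dict[str, list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        per_chrom: dict[str, list[int]] = {}
        for gene in self.annotation:
            per_chrom.setdefault(gene.chrom, []).append(gene.tss_pos)
        self._positions = {c: sorted(p) for c, p in per_chrom.items()}

    def nearest_distance(self, chrom: str, pos: int) -> int | None:
        """Distance in bp from pos to the nearest TSS on chrom, or None."""
        positions = self._positions.get(chrom)
        if not positions:
            return None
        j = bisect_right(positions, pos)
        best = None
        for cand in (j - 1, j):
            if 0 <= cand < len(positions):
                d = abs(positions[cand] - pos)
                best = d if best is None else min(best, d)
        return best
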