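"""Genomic interval primitives and the shared interval-intersection engine.

All coordinates throughout the package are 0-based, half-open (BED
convention).  Inputs in other conventions (RepeatMasker ``.out``,
1-based BED exports) are converted on read and never afterwards.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "BindingSite",
    "intersect",
    "window_around_midpoint",
    "merge_intervals",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open span ``[start, end)`` on a named chromosome.

    Invariants: ``end > start`` and ``start >= 0``.  ``strand`` is one of
    ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand: {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Left-of-center midpoint: ``floor((start + end) / 2)``."""
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap length in bp; 0 when disjoint or on different chroms."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def distance_to_point(self, pos: int) -> int:
        """Distance from ``pos`` to this span; 0 when the point is inside."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0

    def shifted(self, delta: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + delta, self.end + delta,
                               self.strand, self.name)

    def __str__(self) -> str:  # pragma: no cover - repr helper
        return f"{self.chrom}:{self.start}-{self.end}"


def merge_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Merge overlapping/abutting intervals into a disjoint sorted list."""
    per_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in intervals:
        per_chrom.setdefault(iv.chrom, []).append(iv)
    merged: List[GenomicInterval] = []
    for chrom in sorted(per_chrom):
        ivs = sorted(per_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


class IntervalSet:
    """A collection of :class:`GenomicInterval` grouped by chromosome.

    Duplicated intervals are retained (binding *events* are counted, not
    unique loci); coverage computations operate on a merged copy.  Query
    results are independent of insertion order.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome_size: Optional[Dict[str, int]] = None,
        name: Optional[str] = None,
    ) -> None:
        self.name = name
        self.genome_size = dict(genome_size) if genome_size else None
        self._by_chrom: Dict[str, List[GenomicInterval]] = {}
        self._n = 0
        for iv in intervals:
            self.add(iv)
        self._merged_cache: Optional[Dict[str, List[Tuple[int, int]]]] = None

    def add(self, iv: GenomicInterval) -> None:
        lst = self._by_chrom.setdefault(iv.chrom, [])
        lst.append(iv)
        self._n += 1
        self._merged_cache = None

    def __len__(self) -> int:
        return self._n

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in sorted(self._by_chrom):
            yield from sorted(self._by_chrom[chrom], key=lambda i: (i.start, i.end))

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self._by_chrom)

    def on_chrom(self, chrom: str) -> List[GenomicInterval]:
        return sorted(self._by_chrom.get(chrom, []), key=lambda i: (i.start, i.end))

    # -- merged view -----------------------------------------------------

    def _merged(self) -> Dict[str, List[Tuple[int, int]]]:
        if self._merged_cache is None:
            merged: Dict[str, List[Tuple[int, int]]] = {}
            for iv in merge_intervals(iv for lst in self._by_chrom.values() for iv in lst):
                merged.setdefault(iv.chrom, []).append((iv.start, iv.end))
            self._merged_cache = merged
        return self._merged_cache

    def coverage(self, chrom: Optional[str] = None) -> int:
        """Total merged bp covered, per chromosome or overall."""
        merged = self._merged()
        if chrom is not None:
            return sum(e - s for s, e in merged.get(chrom, []))
        return sum(e - s for spans in merged.values() for s, e in spans)

    def genome_fraction(self) -> float:
        if not self.genome_size:
            raise ValueError("genome_size required to compute genome fraction")
        total = sum(self.genome_size.values())
        return self.coverage() / total

    def contains_point(self, chrom: str, pos: int) -> bool:
        """True when ``pos`` falls inside a (merged) interval."""
        spans = self._merged().get(chrom)
        if not spans:
            return False
        starts = [s for s, _ in spans]
        i = bisect_left(starts, pos + 1) - 1
        return i >= 0 and spans[i][0] <= pos < spans[i][1]

    def overlapping(self, query: GenomicInterval, min_overlap_bp: int = 1
                    ) -> List[Tuple[GenomicInterval, int]]:
        """Members overlapping ``query`` by at least ``min_overlap_bp``."""
        out = []
        for iv in self._by_chrom.get(query.chrom, []):
            ov = iv.overlap(query)
            if ov >= min_overlap_bp:
                out.append((iv, ov))
        out.sort(key=lambda t: (t[0].start, t[0].end))
        return out


def intersect(
    a: IntervalSet,
    b: IntervalSet,
    min_overlap_bp: int = 1,
) -> List[Tuple[GenomicInterval, GenomicInterval, int]]:
    """All pairs ``(ia, ib, overlap_bp)`` with overlap >= ``min_overlap_bp``.

    Symmetric in a/b up to pair order; output is deterministically sorted
    and independent of input ordering.  Half-open convention: abutting
    intervals ``[x, y)`` / ``[y, z)`` do not overlap.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    pairs: List[Tuple[GenomicInterval, GenomicInterval, int]] = []
    for chrom in a.chromosomes:
        bs = b.on_chrom(chrom)
        if not bs:
            continue
        b_starts = [iv.start for iv in bs]
        for ia in a.on_chrom(chrom):
            # candidates: every b interval starting before ia.end
            hi = bisect_left(b_starts, ia.end)
            for ib in bs[:hi]:
                ov = min(ia.end, ib.end) - max(ia.start, ib.start)
                if ov >= min_overlap_bp:
                    pairs.append((ia, ib, ov))
    pairs.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[1].start, t[1].end))
    return pairs


def window_around_midpoint(
    peak: GenomicInterval,
    width: int = 200,
    chrom_size: Optional[int] = None,
) -> GenomicInterval:
    """Fixed-width window centered on the peak midpoint.

    ``window = [mid - floor(w/2), mid + ceil(w/2))``; clipped at zero by a
    right shift that preserves the width.  Raises when the chromosome is
    shorter than the window (caller flags & excludes such sites).
    """
    if width < 1:
        raise ValueError("width must be positive")
    mid = peak.midpoint
    start = mid - width // 2
    end = mid + (width - width // 2)
    if start < 0:
        end -= start
        start = 0
    if chrom_size is not None:
        if chrom_size < width:
            raise ValueError(
                f"chromosome {peak.chrom} ({chrom_size} bp) shorter than window {width}")
        if end > chrom_size:
            start -= end - chrom_size
            end = chrom_size
    return GenomicInterval(peak.chrom, start, end, peak.strand, peak.name)


@dataclass
class BindingSite:
    """A TF-binding event: the called peak plus its fixed-width scan window."""

    tf: str
    peak: GenomicInterval
    window_width: int = 200
    site_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.midpoint = self.peak.midpoint
        self.window = window_around_midpoint(self.peak, self.window_width)
        if self.site_id is None:
            self.site_id = f"{self.tf}:{self.peak.chrom}:{self.peak.start}-{self.peak.end}"
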