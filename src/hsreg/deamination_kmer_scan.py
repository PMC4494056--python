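"""C->T mutant enumeration and exact-match genome scanning.

Single-site (and optional double-site) C->T mutants of a seed
oligonucleotide are enumerated over every substring window of the seed
within a configured length range, then counted in genomes by exact,
case-insensitive, gapless matching — the same 100%-identity criterion
used for the wild-type census.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

__all__ = [
    "SeedOligo",
    "MutantEntry",
    "enumerate_mutants",
    "wild_type_windows",
    "scan_genome",
    "per_position_profile",
    "cross_genome_presence",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedOligo:
    """A DNA seed with its cytosine positions labeled C1..Cn in order."""

    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq or any(b not in "ACGT" for b in seq):
            raise ValueError("seed must be non-empty ACGT-only DNA")

    @property
    def c_positions(self) -> Tuple[int, ...]:
        return tuple(i for i, b in enumerate(self.sequence) if b == "C")

    def c_label(self, index: int) -> str:
        """Label (C1..Cn) of the cytosine at sequence index ``index``."""
        return f"C{self.c_positions.index(index) + 1}"


@dataclass(frozen=True)
class MutantEntry:
    sequence: str
    labels: Tuple[str, ...]          # mutated C position label(s)
    length: int
    window: Tuple[int, int]          # source substring [start, end) within seed


def _mutate(sub: str, offsets: Sequence[int]) -> str:
    chars = list(sub)
    for off in offsets:
        assert chars[off] == "C"
        chars[off] = "T"
    return "".join(chars)


def enumerate_mutants(
    seed: SeedOligo,
    min_len: int = 12,
    max_len: int = 24,
    order: int = 1,
    min_len_guard: int = 8,
) -> List[MutantEntry]:
    """All single-site (order 1) or single+double (order 2) C->T mutants.

    For each substring window of the seed with length in
    ``[min_len, max_len]`` and each C (or C pair, order 2) inside it, emit
    the substring with those Cs replaced by T.  Entries are deduplicated
    on (sequence, mutated labels); multi-window provenance keeps the
    first window encountered.  ``min_len`` below ``min_len_guard``
    (default 8) is rejected — shorter k-mers collide all over a genome
    and carry no signal; lower the guard explicitly for toy seeds.
    """
    if min_len < min_len_guard:
        raise ValueError(
            f"min_len {min_len} below collision guard {min_len_guard}")
    if max_len > len(seed.sequence):
        raise ValueError("max_len exceeds seed length")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    seen: Dict[Tuple[str, Tuple[str, ...]], MutantEntry] = {}
    cpos = seed.c_positions
    for start in range(len(seed.sequence)):
        for length in range(min_len, max_len + 1):
            end = start + length
            if end > len(seed.sequence):
                break
            sub = seed.sequence[start:end]
            inside = [p for p in cpos if start <= p < end]
            singles = [(p,) for p in inside]
            combos: List[Tuple[int, ...]] = list(singles)
            if order == 2:
                combos += list(combinations(inside, 2))
            for mut_positions in combos:
                mutant = _mutate(sub, [p - start for p in mut_positions])
                labels = tuple(seed.c_label(p) for p in mut_positions)
                key = (mutant, labels)
                if key not in seen:
                    seen[key] = MutantEntry(mutant, labels, length, (start, end))
    return sorted(seen.values(), key=lambda e: (e.length, e.window, e.labels))


def wild_type_windows(seed: SeedOligo, min_len: int = 12, max_len: int = 24) -> List[str]:
    """Unique wild-type substrings of the seed in the configured length range."""
    subs: Set[str] = set()
    for start in range(len(seed.sequence)):
        for length in range(min_len, max_len + 1):
            if start + length <= len(seed.sequence):
                subs.add(seed.sequence[start:start + length])
    return sorted(subs, key=lambda s: (len(s), s))


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return
        yield i
        start = i + 1  # overlapping occurrences count separately


def scan_genome(
    queries: Sequence[str],
    genome: Dict[str, str],
    strands: str = "both",
) -> Dict[str, int]:
    """Count distinct exact-match loci per query across a genome.

    A locus is (chrom, start, length); with ``strands='both'`` a
    reverse-complement hit contributes the locus of the matched span, so
    palindromic queries never double-count.  Ambiguity codes in the
    genome never match (queries are strict ACGT).
    """
    if strands not in ("forward", "both"):
        raise ValueError("strands must be 'forward' or 'both'")
    upper = {name: seq.upper() for name, seq in genome.items()}
    counts: Dict[str, int] = {}
    for query in queries:
        q = query.upper()
        if any(b not in "ACGT" for b in q):
            raise ValueError(f"non-ACGT base in query {query!r}")
        loci: Set[Tuple[str, int]] = set()
        for chrom, seq in upper.items():
            for i in _find_all(seq, q):
                loci.add((chrom, i))
            if strands == "both":
                rc = reverse_complement(q)
                for i in _find_all(seq, rc):
                    loci.add((chrom, i))
        counts[query] = len(loci)
    return counts


def per_position_profile(
    entries: Sequence[MutantEntry],
    counts: Dict[str, int],
) -> Dict[str, object]:
    """Per-C-position locus totals (order-1 entries) and their asymmetry.

    The asymmetry ratio divides the median of the upper half of the
    per-position totals by the median of the lower half.
    """
    totals: Dict[str, int] = {}
    for entry in entries:
        if len(entry.labels) != 1:
            continue
        totals[entry.labels[0]] = totals.get(entry.labels[0], 0) + counts.get(
            entry.sequence, 0)
    if not totals:
        return {"per_position": {}, "asymmetry_ratio": None}
    ordered = sorted(totals.values())
    half = len(ordered) // 2
    lo = float(np.median(ordered[:half])) if half else float(ordered[0])
    hi = float(np.median(ordered[-half:])) if half else float(ordered[-1])
    ratio = hi / lo if lo > 0 else float("inf")
    per_position = dict(sorted(totals.items(), key=lambda kv: int(kv[0][1:])))
    return {"per_position": per_position, "asymmetry_ratio": ratio}


def cross_genome_presence(
    queries: Sequence[str],
    genomes: Dict[str, Dict[str, str]],
    strands: str = "both",
) -> Dict[str, object]:
    """Presence (>=1 exact locus) of each query in each genome.

    Presence is sequence-level only; positional conservation through
    alignments is out of scope.  Returns the boolean matrix plus
    per-genome and all-genome presence fractions.
    """
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    matrix: Dict[str, Dict[str, bool]] = {}
    for name, genome in genomes.items():
        counts = scan_genome(queries, genome, strands)
        for q in queries:
            matrix.setdefault(q, {})[name] = counts[q] > 0
    n = len(queries)
    per_genome = {name: sum(matrix[q][name] for q in queries) / n if n else 0.0
                  for name in genomes}
    in_all = sum(all(matrix[q].values()) for q in queries) / n if n else 0.0
    return {"matrix": matrix, "per_genome_fraction": per_genome,
            "all_genomes_fraction": in_all}
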