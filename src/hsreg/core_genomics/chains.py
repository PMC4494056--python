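"""UCSC chain format: parsing, validation, writing, and block arithmetic.

A chain records a colinear pairwise alignment between a *target* genome
(the query-side genome the pipeline lifts FROM, e.g. human) and a
*subject* genome.  Header layout::

    chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id
    size dt dq
    ...
    size

Block arithmetic must reconstruct both spans exactly:
``sum(size) + sum(dt) == tEnd - tStart`` and
``sum(size) + sum(dq) == qEnd - qStart``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple

from .intervals import GenomicInterval

__all__ = ["AlignmentChain", "ChainFormatError", "read_chain", "write_chain"]


class ChainFormatError(ValueError):
    """Raised on malformed or arithmetically inconsistent chain input."""


@dataclass
class AlignmentChain:
    chain_id: int
    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    # (size, dt, dq); the final block has dt = dq = 0
    blocks: List[Tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.blocks:
            raise ChainFormatError(f"chain {self.chain_id}: no blocks")
        if any(size <= 0 for size, _, _ in self.blocks):
            raise ChainFormatError(f"chain {self.chain_id}: non-positive block size")
        t_len = sum(s + dt for s, dt, _ in self.blocks)
        q_len = sum(s + dq for s, _, dq in self.blocks)
        if t_len != self.t_end - self.t_start:
            raise ChainFormatError(
                f"chain {self.chain_id}: target arithmetic mismatch "
                f"({t_len} != {self.t_end - self.t_start})")
        if q_len != self.q_end - self.q_start:
            raise ChainFormatError(
                f"chain {self.chain_id}: subject arithmetic mismatch "
                f"({q_len} != {self.q_end - self.q_start})")

    # -- coordinate views ------------------------------------------------

    def target_blocks(self) -> List[Tuple[int, int]]:
        """Aligned block spans ``[start, end)`` in target coordinates."""
        spans = []
        t = self.t_start
        for size, dt, _ in self.blocks:
            spans.append((t, t + size))
            t += size + dt
        return spans

    def subject_blocks_raw(self) -> List[Tuple[int, int]]:
        """Block spans in strand-local subject coordinates."""
        spans = []
        q = self.q_start
        for size, _, dq in self.blocks:
            spans.append((q, q + size))
            q += size + dq
        return spans

    @property
    def target_span(self) -> GenomicInterval:
        return GenomicInterval(self.t_name, self.t_start, self.t_end)

    @property
    def subject_span(self) -> GenomicInterval:
        """Subject span normalized to forward-strand coordinates."""
        if self.q_strand == "-":
            return GenomicInterval(
                self.q_name, self.q_size - self.q_end, self.q_size - self.q_start)
        return GenomicInterval(self.q_name, self.q_start, self.q_end)

    def target_coverage(self, window: GenomicInterval) -> float:
        """Fraction of window bases inside this chain's aligned blocks."""
        if window.chrom != self.t_name:
            return 0.0
        covered = 0
        for s, e in self.target_blocks():
            covered += max(0, min(e, window.end) - max(s, window.start))
        return covered / window.length()

    def map_interval(self, window: GenomicInterval) -> Optional[GenomicInterval]:
        """Project a target interval to forward-strand subject coordinates.

        Returns the minimal subject span covering the projections of all
        overlapping blocks, or None when no block overlaps the window.
        """
        if window.chrom != self.t_name:
            return None
        lo: Optional[int] = None
        hi: Optional[int] = None
        for (ts, te), (qs, qe) in zip(self.target_blocks(), self.subject_blocks_raw()):
            ov_s, ov_e = max(ts, window.start), min(te, window.end)
            if ov_e <= ov_s:
                continue
            m_s = qs + (ov_s - ts)
            m_e = qs + (ov_e - ts)
            lo = m_s if lo is None else min(lo, m_s)
            hi = m_e if hi is None else max(hi, m_e)
        if lo is None:
            return None
        if self.q_strand == "-":
            lo, hi = self.q_size - hi, self.q_size - lo
        return GenomicInterval(self.q_name, lo, hi)


def read_chain(path: str) -> List[AlignmentChain]:
    """Parse every chain in a UCSC chain file, validating block arithmetic."""
    chains: List[AlignmentChain] = []
    header: Optional[List[str]] = None
    blocks: List[Tuple[int, int, int]] = []
    closed = True

    def finish() -> None:
        nonlocal header, blocks, closed
        if header is None:
            return
        if not closed:
            raise ChainFormatError(f"truncated chain (id {header[12]})")
        chains.append(AlignmentChain(
            chain_id=int(header[12]), score=float(header[1]),
            t_name=header[2], t_size=int(header[3]), t_strand=header[4],
            t_start=int(header[5]), t_end=int(header[6]),
            q_name=header[7], q_size=int(header[8]), q_strand=header[9],
            q_start=int(header[10]), q_end=int(header[11]),
            blocks=list(blocks)))
        header, blocks, closed = None, [], True

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if fields[0] == "chain":
                finish()
                if len(fields) != 13:
                    raise ChainFormatError(f"line {lineno}: bad chain header")
                header, blocks, closed = fields, [], False
            else:
                if header is None:
                    raise ChainFormatError(f"line {lineno}: block outside chain")
                if len(fields) == 3:
                    blocks.append((int(fields[0]), int(fields[1]), int(fields[2])))
                elif len(fields) == 1:
                    blocks.append((int(fields[0]), 0, 0))
                    closed = True
                else:
                    raise ChainFormatError(f"line {lineno}: bad block line")
    finish()
    return chains


def write_chain(path: str, chains: Iterable[AlignmentChain]) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score:g} {c.t_name} {c.t_size} {c.t_strand} "
                f"{c.t_start} {c.t_end} {c.q_name} {c.q_size} {c.q_strand} "
                f"{c.q_start} {c.q_end} {c.chain_id}\n")
            for size, dt, dq in c.blocks[:-1]:
                fh.write(f"{size} {dt} {dq}\n")
            fh.write(f"{c.blocks[-1][0]}\n\n")
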