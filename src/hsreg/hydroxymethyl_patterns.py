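"""5hmC proximity to binding sites and the strand-asymmetric three-call
pattern.

The "three-letter" pattern is operationalized as three *consecutive*
hmC calls on a chromosome whose middle call sits on the opposite strand
from the two flanks, with total span at most ``max_span`` bp (default
50, configurable — the published description is verbal/graphical only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .core_genomics import BindingSite, MethylCall
from .enrichment_stats import fisher_2x2

__all__ = [
    "HmcProximityResult",
    "HmcSymbol",
    "hmc_proximity",
    "detect_symbols",
    "symbol_colocalization",
]


@dataclass
class HmcProximityResult:
    tf: str
    window_bp: int
    n_sites: int
    n_with_hmc: int

    @property
    def fraction(self) -> float:
        return self.n_with_hmc / self.n_sites if self.n_sites else 0.0


def _hmc_only(calls: Sequence[MethylCall]) -> List[MethylCall]:
    return [c for c in calls if c.kind == "hmC"]


def hmc_proximity(
    sites: Sequence[BindingSite],
    calls: Sequence[MethylCall],
    windows_bp: Sequence[int] = (100, 1000),
) -> Dict[Tuple[str, int], HmcProximityResult]:
    """Fraction of sites with >=1 hmC call near the midpoint, per window.

    Window membership is half-window distance from the site midpoint with
    a strict bound: a call at ``|pos - mid| < window/2`` counts, so with a
    100-bp window an hmC 40 bp away counts and one 60 bp away does not.
    """
    hmc = _hmc_only(calls)
    by_chrom: Dict[str, List[int]] = {}
    for c in hmc:
        by_chrom.setdefault(c.chrom, []).append(c.position)
    for lst in by_chrom.values():
        lst.sort()

    results: Dict[Tuple[str, int], HmcProximityResult] = {}
    tfs = sorted({s.tf for s in sites})
    for tf in tfs:
        tf_sites = [s for s in sites if s.tf == tf]
        for window in windows_bp:
            half = window / 2
            n_hit = 0
            for site in tf_sites:
                positions = by_chrom.get(site.window.chrom, ())
                if any(abs(p - site.midpoint) < half for p in positions):
                    n_hit += 1
            results[(tf, window)] = HmcProximityResult(tf, window, len(tf_sites), n_hit)
    return results


def compare_tf_fractions(a: HmcProximityResult, b: HmcProximityResult) -> float:
    """Fisher 2x2 p-value comparing two TFs' with-hmC fractions."""
    table = [[a.n_with_hmc, a.n_sites - a.n_with_hmc],
             [b.n_with_hmc, b.n_sites - b.n_with_hmc]]
    return fisher_2x2(table).p_value


@dataclass(frozen=True)
class HmcSymbol:
    """Three hmC calls p1 < p2 < p3 with the middle on the opposite strand."""

    chrom: str
    positions: Tuple[int, int, int]
    strands: Tuple[str, str, str]

    def __post_init__(self) -> None:
        p1, p2, p3 = self.positions
        s1, s2, s3 = self.strands
        if not p1 < p2 < p3:
            raise ValueError("positions must be strictly increasing")
        if not (s1 == s3 and s2 != s1):
            raise ValueError("middle call must oppose the flanks")

    @property
    def span_bp(self) -> int:
        return self.positions[2] - self.positions[0]


def detect_symbols(calls: Sequence[MethylCall], max_span: int = 50) -> List[HmcSymbol]:
    """Every consecutive hmC triple matching the (s, -s, s) strand pattern
    within ``max_span``.  Overlapping symbols are allowed."""
    hmc = _hmc_only(calls)
    by_chrom: Dict[str, List[MethylCall]] = {}
    for c in hmc:
        by_chrom.setdefault(c.chrom, []).append(c)
    symbols: List[HmcSymbol] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda c: c.position)
        for i in range(len(ordered) - 2):
            a, b, c = ordered[i], ordered[i + 1], ordered[i + 2]
            if (a.strand == c.strand and b.strand != a.strand
                    and c.position - a.position <= max_span):
                symbols.append(HmcSymbol(chrom,
                                         (a.position, b.position, c.position),
                                         (a.strand, b.strand, c.strand)))
    return symbols


def symbol_colocalization(
    sites: Sequence[BindingSite],
    symbols: Sequence[HmcSymbol],
    window_bp: int = 1000,
) -> Dict[str, Dict[str, object]]:
    """Per-TF count of sites whose centered window intersects >=1 symbol span.

    A symbol straddling the window edge still counts (intersection rule).
    """
    half = window_bp // 2
    out: Dict[str, Dict[str, object]] = {}
    for tf in sorted({s.tf for s in sites}):
        tf_sites = [s for s in sites if s.tf == tf]
        n_hit = 0
        for site in tf_sites:
            w_start, w_end = site.midpoint - half, site.midpoint + half
            for sym in symbols:
                if sym.chrom != site.window.chrom:
                    continue
                if sym.positions[0] < w_end and sym.positions[2] >= w_start:
                    n_hit += 1
                    break
        out[tf] = {"n_sites": len(tf_sites), "n_with_symbol": n_hit,
                   "fraction": n_hit / len(tf_sites) if tf_sites else 0.0}
    return out


def compare_symbol_counts(a: Dict[str, object], b: Dict[str, object]) -> float:
    """Fisher p comparing two TFs' with-symbol fractions."""
    table = [[a["n_with_symbol"], a["n_sites"] - a["n_with_symbol"]],
             [b["n_with_symbol"], b["n_sites"] - b["n_with_symbol"]]]
    return fisher_2x2(table).p_value
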