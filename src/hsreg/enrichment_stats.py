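"""Shared statistics: hypergeometric/Fisher/chi-square tests, binomial
expectations, Pearson correlation with significance, and chromosome-binned
density profiles."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "hypergeom_tail",
    "fisher_2x2",
    "FisherResult",
    "chi_square_2x2",
    "pearson",
    "binomial_two_sided",
    "DensityProfile",
    "density_profile",
    "profile_correlation",
    "benjamini_hochberg",
]


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p-value, ``P(X >= k)``.

    ``k`` successes observed in ``n`` draws, from a universe of ``N``
    objects of which ``K`` are successes.  Computed in log space by scipy;
    stable for universes up to at least 1e7.
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N:
        raise ValueError(f"inconsistent hypergeometric counts: k={k} n={n} K={K} N={N}")
    # sf(k-1) == P(X >= k); upper tail includes the observed count
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    haldane_corrected: bool = False


def fisher_2x2(table: Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher's exact test with a Haldane-corrected odds ratio.

    The p-value sums the probabilities of all tables at most as likely as
    the observed one (scipy's two-sided convention).  When any cell is
    zero the odds ratio uses the Haldane +0.5 correction and is flagged.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell")
    if (a + b == 0 and c + d == 0) or (a + c == 0 and b + d == 0):
        raise ValueError("all-zero margin")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if 0 in (a, b, c, d):
        orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        return FisherResult(float(p), orat, True)
    return FisherResult(float(p), (a * d) / (b * c), False)


def chi_square_2x2(table: Sequence[Sequence[int]]) -> Tuple[float, float]:
    """Pearson chi-square (no Yates correction) on a 2x2 table."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)


def pearson(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson r with two-sided p from the t distribution (n-2 df).

    Zero-variance input yields ``(nan, nan)`` — an undefined correlation,
    reported as such rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def binomial_two_sided(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p-value for k successes in n trials."""
    return float(stats.binomtest(k, n, p, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# Density profiles

@dataclass
class DensityProfile:
    """Event counts per consecutive left-closed bin ``[i*b, (i+1)*b)``."""

    chrom: str
    bin_size_bp: int
    counts: np.ndarray

    @property
    def n_events(self) -> int:
        return int(self.counts.sum())


def density_profile(
    events: Iterable[Tuple[str, int]],
    chrom_sizes: Dict[str, int],
    bin_size: int,
) -> Dict[str, DensityProfile]:
    """Bin (chrom, position) events into consecutive segments per chromosome."""
    if bin_size < 1:
        raise ValueError("bin_size must be positive")
    profiles = {
        chrom: DensityProfile(chrom, bin_size,
                              np.zeros(math.ceil(size / bin_size), dtype=int))
        for chrom, size in chrom_sizes.items()
    }
    for chrom, pos in events:
        if chrom not in profiles:
            raise ValueError(f"event on unknown chromosome {chrom}")
        if not 0 <= pos < chrom_sizes[chrom]:
            raise ValueError(f"event at {chrom}:{pos} beyond chromosome size")
        profiles[chrom].counts[pos // bin_size] += 1
    return profiles


def profile_correlation(
    a: Dict[str, DensityProfile],
    b: Dict[str, DensityProfile],
    mode: str = "binned",
) -> Tuple[float, float]:
    """Correlate two event distributions.

    ``binned``: over concatenated per-chromosome bin vectors.
    ``per_chrom``: over per-chromosome event totals (one point per
    chromosome) — the default used for chromosome-scale distribution
    comparisons elsewhere in the pipeline.
    """
    chroms = sorted(set(a) & set(b))
    if not chroms:
        raise ValueError("no shared chromosomes")
    if mode == "binned":
        xs = np.concatenate([a[c].counts for c in chroms]).astype(float)
        ys = np.concatenate([b[c].counts for c in chroms]).astype(float)
    elif mode == "per_chrom":
        xs = np.array([a[c].n_events for c in chroms], dtype=float)
        ys = np.array([b[c].n_events for c in chroms], dtype=float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pearson(xs, ys)


def benjamini_hochberg(p_values: Sequence[float]) -> List[float]:
    """BH-adjusted q-values (optional; raw p-values are the default upstream)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out.tolist()
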