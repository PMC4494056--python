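"""LAD/PMD/HMD colocalization of binding sites and domain statistics.

"Within a domain" is decided by the site *midpoint* (domains are >=100 kb
while windows are 200 bp, so boundary effects are negligible — but the
rule must be deterministic).  Random-placement expectations are
``n_sites * genome_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core_genomics import AlignmentChain, BindingSite, GenomicInterval, IntervalSet
from .enrichment_stats import binomial_two_sided, hypergeom_tail
from .lineage_specificity import SiteClassification

__all__ = [
    "DomainPlacementResult",
    "HumanSpecificLad",
    "place_in_domains",
    "derive_human_specific_lads",
    "domain_length_stats",
    "pmd_colocalization",
]


@dataclass
class DomainPlacementResult:
    domain_set: str
    n_sites: int
    n_inside: int
    expected_inside: float
    genome_fraction: float
    p_binomial: float
    p_hypergeom: Optional[float] = None

    @property
    def expected_rounded(self) -> int:
        return round(self.expected_inside)


def place_in_domains(
    sites: Sequence[BindingSite],
    domains: IntervalSet,
    fraction: Optional[float] = None,
    universe: Optional[Sequence[BindingSite]] = None,
) -> DomainPlacementResult:
    """Count sites whose midpoint lies inside a domain vs random expectation.

    ``fraction`` is the domain set's genome fraction; when omitted it is
    derived from ``domains.genome_size``.  The two-sided binomial p tests
    the observed count against ``fraction``; a hypergeometric upper tail
    is added when a finite site ``universe`` is supplied.
    """
    if fraction is None:
        fraction = domains.genome_fraction()
    if not 0 < fraction < 1:
        raise ValueError(f"genome fraction outside (0, 1): {fraction}")
    n = len(sites)
    inside = [s for s in sites if domains.contains_point(s.window.chrom, s.midpoint)]
    k = len(inside)
    expected = n * fraction
    p_binom = binomial_two_sided(k, n, fraction) if n else 1.0
    p_hyper = None
    if universe is not None:
        K = sum(domains.contains_point(s.window.chrom, s.midpoint) for s in universe)
        p_hyper = hypergeom_tail(k, n, K, len(universe))
    return DomainPlacementResult(
        domain_set=domains.name or "domains", n_sites=n, n_inside=k,
        expected_inside=expected, genome_fraction=fraction,
        p_binomial=p_binom, p_hypergeom=p_hyper)


@dataclass
class HumanSpecificLad:
    interval: GenomicInterval
    mapped_span: GenomicInterval
    per_cell_type_outside: Dict[str, bool]


def derive_human_specific_lads(
    human_lads: IntervalSet,
    human_to_mouse_chains: Sequence[AlignmentChain],
    mouse_lad_sets: Dict[str, IntervalSet],
    min_match: float = 0.95,
    overlap_tolerance_bp: int = 0,
) -> List[HumanSpecificLad]:
    """LADs conserved to mouse yet outside mouse LADs in all four cell types.

    A human LAD is retained iff (a) its best chain covers >= ``min_match``
    of it and (b) the mapped mouse span overlaps none of the four mouse
    LAD sets by more than ``overlap_tolerance_bp`` (default: any overlap
    disqualifies).  Refuses to run unless exactly the full panel of four
    cell-type LAD sets is provided — the criterion is conjunctive over
    all of them.
    """
    if len(mouse_lad_sets) != 4:
        raise ValueError(
            f"need all four mouse cell-type LAD sets, got {len(mouse_lad_sets)}")
    retained: List[HumanSpecificLad] = []
    for lad in human_lads:
        best_chain = None
        best_cov = 0.0
        for chain in human_to_mouse_chains:
            cov = chain.target_coverage(lad)
            if cov > best_cov:
                best_cov, best_chain = cov, chain
        if best_chain is None or best_cov < min_match:
            continue  # not conserved to mouse
        mapped = best_chain.map_interval(lad)
        if mapped is None:
            continue
        verdicts = {}
        for cell_type, lad_set in mouse_lad_sets.items():
            ov = sum(o for _, o in lad_set.overlapping(mapped))
            verdicts[cell_type] = ov <= overlap_tolerance_bp
        if all(verdicts.values()):
            retained.append(HumanSpecificLad(lad, mapped, verdicts))
    return retained


def domain_length_stats(
    domains_a: Sequence[GenomicInterval],
    domains_b: Sequence[GenomicInterval],
    test: str = "mannwhitney",
) -> Dict[str, float]:
    """Mean lengths of two domain sets, their b/a fold ratio, and a
    two-sided length-difference p-value (Mann-Whitney default, Welch
    optional)."""
    if not domains_a or not domains_b:
        raise ValueError("empty domain set")
    la = np.array([d.length() for d in domains_a], dtype=float)
    lb = np.array([d.length() for d in domains_b], dtype=float)
    if test == "mannwhitney":
        p = float(stats.mannwhitneyu(la, lb, alternative="two-sided").pvalue)
    elif test == "welch":
        p = float(stats.ttest_ind(la, lb, equal_var=False).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "mean_a": float(la.mean()),
        "mean_b": float(lb.mean()),
        "fold_ratio": round(float(lb.mean() / la.mean()), 1),
        "p_value": p,
    }


def pmd_colocalization(
    classified_sites: Sequence[SiteClassification],
    pmds: IntervalSet,
) -> Dict[Tuple[str, str], Dict[str, float]]:
    """Per (tf, label) inside-PMD fractions with hypergeometric p-values.

    The enrichment universe for each TF/label cell is the TF's full site
    set (all labels), matching the over-representation framing used for
    domain claims.
    """
    out: Dict[Tuple[str, str], Dict[str, float]] = {}
    tfs = sorted({c.tf for c in classified_sites})
    for tf in tfs:
        tf_sites = [c for c in classified_sites if c.tf == tf and c.site is not None]
        universe_inside = [
            c for c in tf_sites
            if pmds.contains_point(c.site.window.chrom, c.site.midpoint)]
        N, K = len(tf_sites), len(universe_inside)
        for label in sorted({c.label for c in tf_sites}):
            sub = [c for c in tf_sites if c.label == label]
            k = sum(pmds.contains_point(c.site.window.chrom, c.site.midpoint)
                    for c in sub)
            n = len(sub)
            out[(tf, label)] = {
                "n_sites": n,
                "n_inside": k,
                "fraction_pct": round(100.0 * k / n, 1) if n else 0.0,
                "p_hypergeom": hypergeom_tail(k, n, K, N) if n else 1.0,
            }
    return out
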