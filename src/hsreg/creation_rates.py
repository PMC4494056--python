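"""Per-lineage creation rates of novel TF-binding sites.

The model is deliberately simple: a lineage that accumulated ``n`` novel
binding sites over ``t`` years created them at ``n / (t / 100,000)`` sites
per 100,000 years, equivalently one site per ``t / n`` years.  Fold
accelerations between lineages are ratios of the *unrounded* per-year
rates, rounded to one decimal only for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

__all__ = [
    "LineageRateInput",
    "rate_per_100k",
    "years_per_site",
    "acceleration",
    "build_rate_table",
    "DEFAULT_TIMELINES_YEARS",
    "HESC_RATE_INPUTS",
]

# Published divergence-time estimates used as default timelines (years):
# modern/archaic human split 370 ka; human-chimp split 13 Ma after the
# 88-Ma Euarchonta/Glires split (75 Myr of shared-primate evolution);
# zebrafish-mouse 350 Myr.
DEFAULT_TIMELINES_YEARS: Dict[str, float] = {
    "modern_human": 370_000,
    "chimpanzee": 75_000_000,
    "mouse": 350_000_000,
}


@dataclass(frozen=True)
class LineageRateInput:
    """Novel-site count attributed to one lineage over one timeline."""

    tf: str
    lineage: str
    n_novel_sites: int
    timeline_years: float

    def __post_init__(self) -> None:
        if self.n_novel_sites < 0:
            raise ValueError("negative site count")
        if self.timeline_years <= 0:
            raise ValueError("timeline must be positive")

    @property
    def rate_per_year(self) -> float:
        return self.n_novel_sites / self.timeline_years


def rate_per_100k(n_novel: int, timeline_years: float) -> float:
    """New binding sites per 100,000 years, to 2 decimal places."""
    if timeline_years <= 0:
        raise ValueError("timeline must be positive")
    if n_novel < 0:
        raise ValueError("negative site count")
    return round(n_novel / (timeline_years / 100_000), 2)


def years_per_site(n_novel: int, timeline_years: float) -> int:
    """Years of evolution per one new binding site, to the nearest integer."""
    if n_novel < 1:
        raise ValueError("years_per_site undefined for zero novel sites")
    if timeline_years <= 0:
        raise ValueError("timeline must be positive")
    return round(timeline_years / n_novel)


def acceleration(numerator: LineageRateInput, denominator: LineageRateInput) -> float:
    """Fold ratio of per-year creation rates, to 1 decimal place.

    Computed from unrounded rates so that display rounding of the
    individual rates never propagates into the ratio.
    """
    if denominator.rate_per_year == 0:
        raise ZeroDivisionError("denominator lineage has zero creation rate")
    return round(numerator.rate_per_year / denominator.rate_per_year, 1)


def build_rate_table(
    inputs: Sequence[LineageRateInput],
    reference_lineages: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Full rate table: one row per (tf, lineage) input.

    ``reference_lineages`` maps a lineage to the lineage its acceleration
    is computed against (e.g. modern_human -> chimpanzee -> mouse).  The
    internal invariant ``rate_per_100k * years_per_site == 100,000`` is
    checked per row before rounding.
    """
    reference_lineages = reference_lineages or {
        "modern_human": "chimpanzee",
        "chimpanzee": "mouse",
    }
    by_key = {(i.tf, i.lineage): i for i in inputs}
    rows = []
    for inp in inputs:
        raw_rate = inp.rate_per_year * 100_000
        if inp.n_novel_sites > 0:
            raw_years = inp.timeline_years / inp.n_novel_sites
            product = raw_rate * raw_years
            if abs(product - 100_000) > 1e-6:
                raise AssertionError(
                    f"rate/years invariant violated for {inp.tf}/{inp.lineage}")
            yps: Optional[int] = years_per_site(inp.n_novel_sites, inp.timeline_years)
        else:
            yps = None
        accel: Optional[float] = None
        ref = reference_lineages.get(inp.lineage)
        if ref is not None and (inp.tf, ref) in by_key:
            accel = acceleration(inp, by_key[(inp.tf, ref)])
        rows.append({
            "tf": inp.tf,
            "lineage": inp.lineage,
            "n_novel_sites": inp.n_novel_sites,
            "timeline_years": inp.timeline_years,
            "rate_per_100k_years": rate_per_100k(inp.n_novel_sites, inp.timeline_years),
            "years_per_site": yps,
            "acceleration_vs_reference": accel,
        })
    return pd.DataFrame(rows)


def mouse_novel_from_totals(mouse_total: int, outgroup_total: int) -> int:
    """Novel mouse sites = mouse total minus fish-outgroup total."""
    n = mouse_total - outgroup_total
    if n < 0:
        raise ValueError("outgroup total exceeds mouse total")
    return n


# Published hESC input counts (novel-site attributions per lineage) used by
# the default report profile and the acceptance script.  The mouse NANOG
# count derives from total-site censuses in mouse (16,667) and zebrafish
# (14,010): 2,657 novel sites over the 350-Myr timeline.
HESC_RATE_INPUTS: List[LineageRateInput] = [
    LineageRateInput("NANOG", "mouse",
                     mouse_novel_from_totals(16_667, 14_010),
                     DEFAULT_TIMELINES_YEARS["mouse"]),
    LineageRateInput("NANOG", "chimpanzee", 28_304, DEFAULT_TIMELINES_YEARS["chimpanzee"]),
    LineageRateInput("NANOG", "modern_human", 794, DEFAULT_TIMELINES_YEARS["modern_human"]),
    LineageRateInput("CTCF", "chimpanzee", 28_427, DEFAULT_TIMELINES_YEARS["chimpanzee"]),
    LineageRateInput("CTCF", "modern_human", 591, DEFAULT_TIMELINES_YEARS["modern_human"]),
    LineageRateInput("POU5F1", "chimpanzee", 11_617, DEFAULT_TIMELINES_YEARS["chimpanzee"]),
    LineageRateInput("POU5F1", "modern_human", 2_386, DEFAULT_TIMELINES_YEARS["modern_human"]),
    LineageRateInput("RNAPII", "chimpanzee", 11_693, DEFAULT_TIMELINES_YEARS["chimpanzee"]),
    LineageRateInput("RNAPII", "modern_human", 319, DEFAULT_TIMELINES_YEARS["modern_human"]),
]
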