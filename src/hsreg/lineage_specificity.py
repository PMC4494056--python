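"""Chain-based liftability classification of binding-site windows.

A window "intersects a chain" when the fraction of its bases falling
inside the best single chain's aligned blocks reaches ``min_match``
(default 0.95).  A site deleted in mouse AND rat is primate-specific; a
primate-specific site additionally deleted in every non-human panel
species and uniquely mappable under same-species alternate-assembly
chains is human-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import pandas as pd

from .core_genomics import AlignmentChain, BindingSite, GenomicInterval

__all__ = [
    "LiftVerdict",
    "SiteClassification",
    "assess_liftability",
    "classify_sites",
    "classification_summary",
    "DEFAULT_RODENTS",
]

logger = logging.getLogger(__name__)

DEFAULT_RODENTS = ("mouse", "rat")

STATUS_MAPS_UNIQUE = "maps_unique"
STATUS_MAPS_MULTI = "maps_multi"
STATUS_DELETED = "deleted"


@dataclass(frozen=True)
class LiftVerdict:
    species: str
    status: str
    best_coverage_fraction: float
    site_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.best_coverage_fraction <= 1.0:
            raise ValueError("coverage outside [0, 1]")


@dataclass
class SiteClassification:
    site_id: str
    tf: str
    label: str  # shared / primate_specific / human_specific / unassessable
    evidence: Dict[str, LiftVerdict] = field(default_factory=dict)
    dual_assembly_unique: bool = False
    site: Optional[BindingSite] = None


def assess_liftability(
    window: GenomicInterval,
    chains: Sequence[AlignmentChain],
    min_match: float = 0.95,
    species: str = "",
) -> LiftVerdict:
    """Liftability verdict for one window against one species' chain set.

    Coverage per chain = window bases inside that chain's aligned blocks
    divided by window length.  ``deleted`` iff no chain reaches
    ``min_match``; ``maps_unique`` iff exactly one does.
    """
    if not 0 < min_match <= 1:
        raise ValueError("min_match must be in (0, 1]")
    best = 0.0
    n_hits = 0
    for chain in chains:
        cov = chain.target_coverage(window)
        best = max(best, cov)
        if cov >= min_match:
            n_hits += 1
    if n_hits == 0:
        if best == 0.0:
            logger.debug("window %s absent from all chains for %s", window, species)
        status = STATUS_DELETED
    elif n_hits == 1:
        status = STATUS_MAPS_UNIQUE
    else:
        status = STATUS_MAPS_MULTI
    return LiftVerdict(species=species, status=status, best_coverage_fraction=best)


def classify_sites(
    sites: Sequence[BindingSite],
    panel: Dict[str, Sequence[AlignmentChain]],
    human_alt_assembly_chains: Optional[Sequence[AlignmentChain]] = None,
    min_match: float = 0.95,
    rodent_species: Sequence[str] = DEFAULT_RODENTS,
) -> List[SiteClassification]:
    """Label every site shared / primate_specific / human_specific.

    ``panel`` maps species name to its chain set; species beyond the
    rodents are treated as the primate panel.  When rodent chains are
    missing entirely, every site is unassessable (hard warning) — the
    rodent criterion anchors the whole classification.
    """
    missing_rodents = [sp for sp in rodent_species if sp not in panel]
    if missing_rodents:
        logger.warning("missing rodent chain sets %s: all sites unassessable",
                       missing_rodents)
        return [SiteClassification(s.site_id, s.tf, "unassessable", site=s)
                for s in sites]

    primate_panel = [sp for sp in panel if sp not in rodent_species]
    out: List[SiteClassification] = []
    for site in sites:
        evidence = {
            sp: LiftVerdict(sp, v.status, v.best_coverage_fraction, site.site_id)
            for sp, v in ((sp, assess_liftability(site.window, panel[sp],
                                                  min_match, sp))
                          for sp in panel)
        }
        deleted = {sp for sp, v in evidence.items() if v.status == STATUS_DELETED}
        primate_specific = all(sp in deleted for sp in rodent_species)

        dual_unique = False
        if human_alt_assembly_chains is not None:
            alt = assess_liftability(site.window, human_alt_assembly_chains,
                                     min_match, "alt_assembly")
            evidence["alt_assembly"] = LiftVerdict(
                "alt_assembly", alt.status, alt.best_coverage_fraction, site.site_id)
            dual_unique = alt.status == STATUS_MAPS_UNIQUE

        human_specific = (
            primate_specific
            and all(sp in deleted for sp in primate_panel)
            and bool(primate_panel)
            and dual_unique
        )
        label = ("human_specific" if human_specific
                 else "primate_specific" if primate_specific
                 else "shared")
        out.append(SiteClassification(site.site_id, site.tf, label, evidence,
                                      dual_unique, site))
    return out


def _table_pct(count: int, total: int) -> str:
    """Summary-table percent formatting: integers at >=10%, 1 dp below."""
    if total == 0:
        return "0%"
    pct = 100.0 * count / total
    return f"{round(pct)}%" if pct >= 9.5 else f"{pct:.1f}%"


def classification_summary(classifications: Sequence[SiteClassification]) -> pd.DataFrame:
    """Per-TF totals with primate-/human-specific counts and percentages.

    Unassessable sites are excluded from denominators and reported in
    their own column.  Nesting invariant: every human-specific site is
    also primate-specific.
    """
    rows = []
    for tf in sorted({c.tf for c in classifications}):
        sub = [c for c in classifications if c.tf == tf]
        unassessable = sum(c.label == "unassessable" for c in sub)
        assessable = len(sub) - unassessable
        primate = sum(c.label in ("primate_specific", "human_specific") for c in sub)
        human = sum(c.label == "human_specific" for c in sub)
        assert human <= primate
        rows.append({
            "tf": tf,
            "total_sites": assessable,
            "unassessable": unassessable,
            "primate_specific": primate,
            "primate_specific_pct": _table_pct(primate, assessable),
            "human_specific": human,
            "human_specific_pct": _table_pct(human, assessable),
        })
    return pd.DataFrame(rows)
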