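"""Overlap of binding-site windows with repeat annotations.

Tabulates, per TF, how many site windows fall within repeats, the family
breakdown, the LTR/LINE-embedded fraction, and a full-length/truncated
census of L1 copies.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .core_genomics import BindingSite, RepeatAnnotation

__all__ = [
    "RepeatAssociationReport",
    "L1CompletenessCall",
    "annotate_repeat_overlap",
    "tabulate_families",
    "classify_l1_completeness",
    "FULL_LENGTH_L1_BOUNDS",
]

logger = logging.getLogger(__name__)

# Full-length L1 size window in bp (bounds configurable at call sites).
FULL_LENGTH_L1_BOUNDS = (5962, 6189)

LTR_LINE_CLASSES = ("LTR", "LINE")


@dataclass
class TfRepeatSummary:
    tf: str
    n_sites: int
    n_in_repeats: int
    family_counts: Counter = field(default_factory=Counter)
    class_counts: Counter = field(default_factory=Counter)

    @property
    def pct_in_repeats(self) -> float:
        return round(100.0 * self.n_in_repeats / self.n_sites, 1) if self.n_sites else 0.0

    @property
    def n_in_ltr_line(self) -> int:
        return sum(self.class_counts[c] for c in LTR_LINE_CLASSES)

    @property
    def pct_in_ltr_line(self) -> float:
        return round(100.0 * self.n_in_ltr_line / self.n_sites, 1) if self.n_sites else 0.0


@dataclass
class RepeatAssociationReport:
    per_tf: Dict[str, TfRepeatSummary]
    # site_id -> (best-overlap annotation, overlap bp); absent when no overlap
    assignments: Dict[str, Tuple[RepeatAnnotation, int]]
    # raw per-pair table (site_id, annotation, overlap bp)
    pairs: List[Tuple[str, RepeatAnnotation, int]]


def annotate_repeat_overlap(
    sites: Sequence[BindingSite],
    repeats: Sequence[RepeatAnnotation],
    min_overlap_bp: int = 1,
) -> RepeatAssociationReport:
    """Assign each site window to the repeat it overlaps the most.

    A site is "within repeats" iff its window overlaps at least one
    repeat by ``min_overlap_bp`` or more (default 1 — the most permissive
    reading).  Each in-repeat site counts exactly once, assigned to the
    maximal-overlap repeat (ties broken toward the lower start
    coordinate), so family counts sum to ``n_in_repeats``.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    by_chrom: Dict[str, List[RepeatAnnotation]] = {}
    for ann in repeats:
        by_chrom.setdefault(ann.interval.chrom, []).append(ann)
    for lst in by_chrom.values():
        lst.sort(key=lambda a: (a.interval.start, a.interval.end))

    per_tf: Dict[str, TfRepeatSummary] = {}
    assignments: Dict[str, Tuple[RepeatAnnotation, int]] = {}
    pairs: List[Tuple[str, RepeatAnnotation, int]] = []
    for site in sorted(sites, key=lambda s: (s.tf, s.window.chrom, s.window.start)):
        summary = per_tf.setdefault(site.tf, TfRepeatSummary(site.tf, 0, 0))
        summary.n_sites += 1
        best: Optional[Tuple[RepeatAnnotation, int]] = None
        for ann in by_chrom.get(site.window.chrom, ()):
            ov = ann.interval.overlap(site.window)
            if ov >= min_overlap_bp:
                pairs.append((site.site_id, ann, ov))
                if best is None or ov > best[1]:
                    best = (ann, ov)
        if best is not None:
            assignments[site.site_id] = best
            summary.n_in_repeats += 1
            summary.family_counts[best[0].repeat_name] += 1
            summary.class_counts[best[0].repeat_class] += 1
    return RepeatAssociationReport(per_tf, assignments, pairs)


def tabulate_families(report: RepeatAssociationReport) -> Dict[str, Dict[str, object]]:
    """Family and class breakdown per TF, with the LTR/LINE-embedded fraction."""
    out: Dict[str, Dict[str, object]] = {}
    for tf, summary in sorted(report.per_tf.items()):
        assert sum(summary.family_counts.values()) == summary.n_in_repeats
        out[tf] = {
            "n_sites": summary.n_sites,
            "n_in_repeats": summary.n_in_repeats,
            "pct_in_repeats": summary.pct_in_repeats,
            "family_counts": dict(sorted(summary.family_counts.items())),
            "class_counts": dict(sorted(summary.class_counts.items())),
            "n_in_ltr_line": summary.n_in_ltr_line,
            "pct_in_ltr_line": summary.pct_in_ltr_line,
        }
    return out


@dataclass(frozen=True)
class L1CompletenessCall:
    repeat: RepeatAnnotation
    length_bp: int
    divergence_pct: Optional[float]
    call: str  # full_length / truncated


def classify_l1_completeness(
    repeats: Sequence[RepeatAnnotation],
    bounds: Tuple[int, int] = FULL_LENGTH_L1_BOUNDS,
    max_divergence_pct: Optional[float] = None,
) -> List[L1CompletenessCall]:
    """Call each L1-family copy full_length or truncated by its span length.

    ``full_length`` iff ``bounds[0] <= length <= bounds[1]``.  Non-L1
    annotations are skipped with a log note; an optional divergence cap
    restricts the census to young copies.
    """
    lo, hi = bounds
    calls: List[L1CompletenessCall] = []
    for ann in repeats:
        if not ann.repeat_name.startswith("L1"):
            logger.debug("skipping non-L1 annotation %s", ann.repeat_name)
            continue
        if (max_divergence_pct is not None and ann.divergence_pct is not None
                and ann.divergence_pct >= max_divergence_pct):
            continue
        length = ann.length()
        call = "full_length" if lo <= length <= hi else "truncated"
        calls.append(L1CompletenessCall(ann, length, ann.divergence_pct, call))
    return calls
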