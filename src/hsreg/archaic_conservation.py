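"""Conservation of site sequences across individual modern/archaic genomes.

Default conservation is full-length 100% identity between the reference
window sequence and the sequence retrieved from the individual genome;
the identity threshold is exposed.  Cells with no retrievable sequence
are *uncallable* and excluded from denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "PRESENT",
    "ABSENT",
    "UNCALLABLE",
    "ConservationMatrix",
    "score_conservation",
    "cohort_summary",
    "attribute_era",
]

PRESENT = "present"
ABSENT = "absent"
UNCALLABLE = "uncallable"

ERA_MODERN = "modern"
ERA_ARCHAIC = "archaic"


@dataclass
class Individual:
    """One individual genome: either site sequences or precomputed calls."""

    individual_id: str
    era: str  # modern / archaic
    sequences: Optional[Dict[str, Optional[str]]] = None  # site_id -> seq
    presence_calls: Optional[Dict[str, bool]] = None

    def __post_init__(self) -> None:
        if self.era not in (ERA_MODERN, ERA_ARCHAIC):
            raise ValueError(f"bad era {self.era!r}")
        if (self.sequences is None) == (self.presence_calls is None):
            raise ValueError("provide exactly one of sequences / presence_calls")


@dataclass
class ConservationMatrix:
    site_ids: List[str]
    individuals: List[Tuple[str, str]]  # (id, era)
    cells: pd.DataFrame  # index site_ids, columns individual ids, values status

    def era_columns(self, era: str) -> List[str]:
        return [iid for iid, e in self.individuals if e == era]


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    matches = sum(x == y for x, y in zip(a[:n].upper(), b[:n].upper()))
    return matches / max(len(a), len(b))


def score_conservation(
    site_ids: Sequence[str],
    reference_sequences: Dict[str, str],
    individuals: Sequence[Individual],
    min_identity: float = 1.0,
    full_length: bool = True,
) -> ConservationMatrix:
    """Presence matrix of site sequences across individual genomes.

    A cell is ``present`` iff the individual's retrieved sequence covers
    the full window (when ``full_length``) and its identity to the
    reference reaches ``min_identity``.  Missing sequences — and length
    mismatches under ``full_length`` — are ``uncallable``.
    """
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    data: Dict[str, List[str]] = {}
    for ind in individuals:
        col = []
        for sid in site_ids:
            if ind.presence_calls is not None:
                if sid not in ind.presence_calls:
                    col.append(UNCALLABLE)
                else:
                    col.append(PRESENT if ind.presence_calls[sid] else ABSENT)
                continue
            seq = ind.sequences.get(sid)
            ref = reference_sequences.get(sid)
            if seq is None or ref is None:
                col.append(UNCALLABLE)
                continue
            if full_length and len(seq) != len(ref):
                col.append(UNCALLABLE)
                continue
            col.append(PRESENT if _identity(seq, ref) >= min_identity else ABSENT)
        data[ind.individual_id] = col
    cells = pd.DataFrame(data, index=list(site_ids))
    return ConservationMatrix(list(site_ids),
                              [(i.individual_id, i.era) for i in individuals],
                              cells)


def cohort_summary(matrix: ConservationMatrix) -> Dict[str, object]:
    """Per-individual conservation %, conserved-in-all and -in-any over the
    modern-era columns; percentages to 1 dp, uncallable cells excluded
    from per-individual denominators."""
    per_individual: Dict[str, float] = {}
    for iid, _era in matrix.individuals:
        col = matrix.cells[iid]
        callable_mask = col != UNCALLABLE
        n_callable = int(callable_mask.sum())
        n_present = int((col == PRESENT).sum())
        per_individual[iid] = round(100.0 * n_present / n_callable, 1) if n_callable else float("nan")

    modern = matrix.era_columns(ERA_MODERN)
    sub = matrix.cells[modern]
    n_rows = len(sub)
    in_all = int((sub == PRESENT).all(axis=1).sum())
    in_any = int((sub == PRESENT).any(axis=1).sum())
    return {
        "per_individual_pct": per_individual,
        "conserved_in_all": in_all,
        "conserved_in_all_pct": round(100.0 * in_all / n_rows, 1) if n_rows else 0.0,
        "conserved_in_any": in_any,
        "conserved_in_any_pct": round(100.0 * in_any / n_rows, 1) if n_rows else 0.0,
    }


def attribute_era(matrix: ConservationMatrix, split_years: float = 370_000
                  ) -> Dict[str, object]:
    """Attribute each site's emergence relative to the archaic split.

    A site is post-split iff *no* archaic individual shows it present.
    post_split + archaic_present partition the assessable sites exactly;
    both fractions are reported.
    """
    archaic = matrix.era_columns(ERA_ARCHAIC)
    if not archaic:
        raise ValueError("need at least one archaic individual")
    sub = matrix.cells[archaic]
    archaic_present_mask = (sub == PRESENT).any(axis=1)
    n = len(sub)
    n_archaic_present = int(archaic_present_mask.sum())
    n_post_split = n - n_archaic_present
    return {
        "split_years": split_years,
        "n_assessable": n,
        "n_post_split": n_post_split,
        "post_split_fraction": n_post_split / n if n else 0.0,
        "n_archaic_present": n_archaic_present,
        "archaic_present_fraction": n_archaic_present / n if n else 0.0,
        "post_split_site_ids": [sid for sid, post in
                                zip(matrix.site_ids, ~archaic_present_mask) if post],
    }
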