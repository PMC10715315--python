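"""Ranked screening orders.

Five strategies for ordering a cohort's subsequent-screen visits, plus
covariate-based comparators and a cross-site merge:

* A — uniform random order (the standardized-interval baseline);
* B — all mild DR before all no DR, random within each grade block;
* C — grade blocks, descending baseline HbA1c within each;
* D — descending model progression score (max over eyes);
* E — the observed attendance order;
* covariate comparators — grade blocks, then descending age or diabetes
  duration, or insulin users first, within each block;
* a normalized-rank merge that combines per-site orders into one list
  while preserving each site's internal prioritization.

Deterministic sorts break exact ties by patient_id so every ranking is
fully reproducible; randomized strategies take a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, MILD, patient_score

__all__ = [
    "RankedList",
    "rank_random",
    "rank_grade_random",
    "rank_grade_hba1c",
    "rank_model",
    "rank_observed",
    "rank_covariate",
    "combine_sites",
    "STRATEGIES",
]

STRATEGIES = (
    "A_random",
    "B_grade_random",
    "C_grade_hba1c",
    "D_model",
    "E_observed",
    "COV_age",
    "COV_duration",
    "COV_insulin",
    "COV_grade_only",
)


@dataclass
class RankedList:
    """An ordering of a cohort's patients produced by one strategy."""

    strategy: str
    order: list[str]
    run_index: int = 0
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.order)

    def positions(self) -> dict[str, int]:
        """patient_id -> 1-based position in the list."""
        return {pid: i + 1 for i, pid in enumerate(self.order)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.order) + 1),
                "patient_id": self.order,
                "strategy": self.strategy,
                "run_index": self.run_index,
                "seed": self.seed,
            }
        )


def _grade_key(p) -> int:
    # Mild DR first.
    return 0 if p.baseline_grade == MILD else 1


def rank_random(cohort: Cohort, seed: int, run_index: int = 0) -> RankedList:
    """Approach A: uniform random permutation."""
    rng = np.random.default_rng(seed)
    ids = list(cohort.patient_ids)
    order = [ids[i] for i in rng.permutation(len(ids))]
    return RankedList("A_random", order, run_index=run_index, seed=seed)


def rank_grade_random(cohort: Cohort, seed: int, run_index: int = 0) -> RankedList:
    """Approach B: all mild DR then all no DR, uniform within each block."""
    rng = np.random.default_rng(seed)
    mild = [p.patient_id for p in cohort if p.baseline_grade == MILD]
    nodr = [p.patient_id for p in cohort if p.baseline_grade != MILD]
    order = [mild[i] for i in rng.permutation(len(mild))]
    order += [nodr[i] for i in rng.permutation(len(nodr))]
    return RankedList("B_grade_random", order, run_index=run_index, seed=seed)


def rank_grade_hba1c(cohort: Cohort) -> RankedList:
    """Approach C: grade blocks, descending baseline HbA1c within each.

    Requires HbA1c for every patient (the eligibility filter guarantees
    this on study-rule cohorts); exact ties fall back to patient_id.
    """
    missing = [p.patient_id for p in cohort if p.hba1c_percent is None]
    if missing:
        raise ValueError(f"HbA1c missing for eligible patients: {missing[:5]}")
    ranked = sorted(cohort, key=lambda p: (_grade_key(p), -p.hba1c_percent, p.patient_id))
    return RankedList("C_grade_hba1c", [p.patient_id for p in ranked])


def rank_model(cohort: Cohort) -> RankedList:
    """Approach D: descending model score (max over present eye scores)."""
    ranked = sorted(cohort, key=lambda p: (-patient_score(p), p.patient_id))
    return RankedList("D_model", [p.patient_id for p in ranked])


def rank_observed(cohort: Cohort) -> RankedList:
    """Approach E: the order patients actually attended (ascending
    attended_day, patient_id on same-day ties)."""
    missing = [p.patient_id for p in cohort if p.attended_day is None]
    if missing:
        raise ValueError(f"attended_day missing for patients: {missing[:5]}")
    ranked = sorted(cohort, key=lambda p: (p.attended_day, p.patient_id))
    return RankedList("E_observed", [p.patient_id for p in ranked])


def rank_covariate(
    cohort: Cohort, covariate: str, seed: int = 0, run_index: int = 0
) -> RankedList:
    """Grade blocks, then one extra baseline variable within each block.

    covariate: "age" or "duration" (descending, patient_id tie-break),
    "insulin" (users before non-users, random order within each level),
    or "grade_only" (random within each grade block — the grade-alone
    comparator).  The covariate must be present ("yes"/"no" for insulin)
    for every patient: run on the complete-case subset.
    """
    rng = np.random.default_rng(seed)

    if covariate == "grade_only":
        return RankedList(
            "COV_grade_only",
            rank_grade_random(cohort, seed).order,
            run_index=run_index,
            seed=seed,
        )
    if covariate in ("age", "duration"):
        attr = "age_years" if covariate == "age" else "diabetes_duration_years"
        missing = [p.patient_id for p in cohort if getattr(p, attr) is None]
        if missing:
            raise ValueError(f"{covariate} missing for patients: {missing[:5]}")
        ranked = sorted(cohort, key=lambda p: (_grade_key(p), -getattr(p, attr), p.patient_id))
        return RankedList(f"COV_{covariate}", [p.patient_id for p in ranked], run_index, seed)
    if covariate == "insulin":
        missing = [p.patient_id for p in cohort if p.insulin_use == "unknown"]
        if missing:
            raise ValueError(f"insulin use unknown for patients: {missing[:5]}")
        order: list[str] = []
        for grade in (0, 1):
            for level in ("yes", "no"):
                ids = [
                    p.patient_id
                    for p in cohort
                    if _grade_key(p) == grade and p.insulin_use == level
                ]
                order += [ids[i] for i in rng.permutation(len(ids))]
        return RankedList("COV_insulin", order, run_index=run_index, seed=seed)
    raise ValueError(f"unknown covariate {covariate!r}")


def combine_sites(
    per_site: Sequence[tuple[str, RankedList, int]], strategy: Optional[str] = None
) -> RankedList:
    """Merge per-site rankings into one global order.

    Each patient is keyed by their normalized within-site rank
    (position - 0.5) / site_size; the global list sorts ascending on that
    key, so equally-prioritized patients from different-sized sites
    interleave proportionally and every site's internal order is
    preserved.  Exact key ties go to the larger site, then patient_id.
    """
    seen: set[str] = set()
    keyed = []
    for site_id, ranked, site_size in per_site:
        dup = seen.intersection(ranked.order)
        if dup:
            raise ValueError(f"patients appear in more than one site: {sorted(dup)[:5]}")
        seen.update(ranked.order)
        for pos, pid in enumerate(ranked.order, start=1):
            keyed.append(((pos - 0.5) / site_size, -site_size, pid))
    keyed.sort()
    name = strategy or (per_site[0][1].strategy if per_site else "combined")
    return RankedList(name, [pid for _, _, pid in keyed])
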