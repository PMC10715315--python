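"""Analysis-inclusion filters with a CONSORT-style exclusion log.

A patient enters the analysis only if they attended the subsequent screen
within a tolerated window of their appointment, not implausibly soon
after baseline, and with the data the analysis requires (HbA1c, a
gradable image, a known MOD+ outcome).  Each excluded patient is counted
under exactly one reason — the first failing rule in a fixed precedence
order — so the reason counts plus the eligible count always partition the
input cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .cohort import Cohort

__all__ = ["EligibilityRules", "ExclusionLog", "apply_eligibility", "EXCLUSION_REASONS"]

EXCLUSION_REASONS = (
    "no_followup",
    "attended_early",
    "outside_window",
    "missing_hba1c",
    "ungradable_image",
    "unknown_outcome",
)


@dataclass
class EligibilityRules:
    """Filter thresholds.

    Defaults reproduce the study rules: attendance within +/-60 days of the
    appointment (boundary inclusive), at least 150 days after baseline
    (strictly earlier attendance is excluded), and required HbA1c,
    gradable image and known outcome.
    """

    appointment_window_days: int = 60
    min_days_since_baseline: int = 150
    require_hba1c: bool = True
    require_gradable_image: bool = True
    require_known_outcome: bool = True

    def __post_init__(self) -> None:
        if self.appointment_window_days < 0 or self.min_days_since_baseline < 0:
            raise ValueError("day thresholds must be >= 0")


@dataclass
class ExclusionLog:
    counts: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in EXCLUSION_REASONS}
    )
    per_patient: dict[str, str] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())

    def to_json(self) -> str:
        return json.dumps({"counts": self.counts, "per_patient": self.per_patient}, indent=2)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"reason": list(self.counts), "count": list(self.counts.values())}
        ).to_csv(path, index=False)


def _first_failure(p, rules: EligibilityRules) -> str | None:
    if p.attended_day is None:
        return "no_followup"
    if p.attended_day < rules.min_days_since_baseline:
        return "attended_early"
    # A present attendance with no appointment on record cannot satisfy the
    # window rule, so it falls under outside_window.
    if p.appointment_day is None or abs(p.attended_day - p.appointment_day) > rules.appointment_window_days:
        return "outside_window"
    if rules.require_hba1c and p.hba1c_percent is None:
        return "missing_hba1c"
    if rules.require_gradable_image and not p.gradable_image:
        return "ungradable_image"
    if rules.require_known_outcome and p.outcome_mod_plus is None:
        return "unknown_outcome"
    return None


def apply_eligibility(
    cohort: Cohort, rules: EligibilityRules | None = None
) -> tuple[Cohort, ExclusionLog]:
    """Split a cohort into the analysis-eligible subset and an exclusion log.

    Precedence of reasons follows ``EXCLUSION_REASONS``; the first failing
    rule wins.  An empty eligible set is a valid output.
    """
    rules = rules or EligibilityRules()
    log = ExclusionLog()
    eligible = []
    for p in cohort:
        reason = _first_failure(p, rules)
        if reason is None:
            eligible.append(p)
        else:
            log.counts[reason] += 1
            log.per_patient[p.patient_id] = reason
    return Cohort(patients=eligible, provenance=cohort.provenance), log
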