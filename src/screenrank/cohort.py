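"""Patient records and cohort container.

A cohort is one screening round: every patient attended a baseline visit,
was graded as having no or mild diabetic retinopathy (DR), received a
per-eye progression score, and was given an appointment for a subsequent
screen roughly a year later.  The binary endpoint is progression to
moderate-or-worse (MOD+) DR at that subsequent screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "NO_DR",
    "MILD",
    "PatientRecord",
    "Cohort",
    "patient_score",
    "MissingScoreError",
]

NO_DR = "NO_DR"
MILD = "MILD"

CSV_COLUMNS = [
    "patient_id",
    "site_id",
    "baseline_grade",
    "hba1c_percent",
    "age_years",
    "diabetes_duration_years",
    "insulin_use",
    "score_left",
    "score_right",
    "appointment_day",
    "attended_day",
    "gradable_image",
    "outcome_mod_plus",
]


class MissingScoreError(ValueError):
    """Raised when a patient has no per-eye progression score at all."""


@dataclass
class PatientRecord:
    """One screened patient.

    ``baseline_grade`` is ``"NO_DR"`` or ``"MILD"``; ``insulin_use`` is
    ``"yes"``, ``"no"`` or ``"unknown"``; ``outcome_mod_plus`` is True/False
    or None when the subsequent-visit grade is unknown.  Day fields are
    integer offsets from the baseline visit.  Missing values are None.
    """

    patient_id: str
    site_id: str
    baseline_grade: str
    hba1c_percent: Optional[float] = None
    age_years: Optional[float] = None
    diabetes_duration_years: Optional[float] = None
    insulin_use: str = "unknown"
    score_left: Optional[float] = None
    score_right: Optional[float] = None
    appointment_day: Optional[int] = None
    attended_day: Optional[int] = None
    gradable_image: bool = True
    outcome_mod_plus: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.baseline_grade not in (NO_DR, MILD):
            raise ValueError(f"baseline_grade must be NO_DR or MILD, got {self.baseline_grade!r}")
        if self.insulin_use not in ("yes", "no", "unknown"):
            raise ValueError(f"insulin_use must be yes/no/unknown, got {self.insulin_use!r}")
        if self.attended_day is not None and self.attended_day < 0:
            raise ValueError("attended_day must be >= 0 when present")
        for eye in ("score_left", "score_right"):
            s = getattr(self, eye)
            if s is not None and not 0.0 <= s <= 1.0:
                raise ValueError(f"{eye} must lie in [0, 1], got {s}")


def patient_score(record: PatientRecord) -> float:
    """Patient-level progression score: the maximum over present eye scores.

    The risk model scores each eye separately; patients are prioritized by
    their worse (higher-risk) eye.

    Raises
    ------
    MissingScoreError
        If both eye scores are missing.
    """
    scores = [s for s in (record.score_left, record.score_right) if s is not None]
    if not scores:
        raise MissingScoreError(f"patient {record.patient_id}: both eye scores missing")
    return max(scores)


@dataclass
class Cohort:
    """An ordered collection of patients with unique ids.

    ``provenance`` records where the cohort came from (a simulation config
    or a source-file path); it is carried along but never interpreted.
    """

    patients: list[PatientRecord] = field(default_factory=list)
    provenance: object = None

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError("patient_id values must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    def __getitem__(self, patient_id: str) -> PatientRecord:
        return self._index()[patient_id]

    def _index(self) -> dict[str, PatientRecord]:
        return {p.patient_id: p for p in self.patients}

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def outcomes(self) -> dict[str, bool]:
        """Map patient_id -> MOD+ outcome for patients with a known outcome."""
        return {
            p.patient_id: p.outcome_mod_plus
            for p in self.patients
            if p.outcome_mod_plus is not None
        }

    def subset(self, patient_ids: Iterable[str]) -> "Cohort":
        keep = set(patient_ids)
        return Cohort(
            patients=[p for p in self.patients if p.patient_id in keep],
            provenance=self.provenance,
        )

    def sites(self) -> list[str]:
        """Site ids in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.patients:
            seen.setdefault(p.site_id, None)
        return list(seen)

    # ---- CSV round trip (pandas-backed) -------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "site_id": p.site_id,
                    "baseline_grade": p.baseline_grade,
                    "hba1c_percent": p.hba1c_percent,
                    "age_years": p.age_years,
                    "diabetes_duration_years": p.diabetes_duration_years,
                    "insulin_use": p.insulin_use,
                    "score_left": p.score_left,
                    "score_right": p.score_right,
                    "appointment_day": p.appointment_day,
                    "attended_day": p.attended_day,
                    "gradable_image": int(p.gradable_image),
                    "outcome_mod_plus": (
                        "unknown" if p.outcome_mod_plus is None else int(p.outcome_mod_plus)
                    ),
                }
            )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: object = None) -> "Cohort":
        def _opt(v):
            if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
                return None
            return v

        patients = []
        for row in frame.itertuples(index=False):
            outcome = _opt(row.outcome_mod_plus)
            if outcome is not None and outcome != "unknown":
                outcome = bool(int(outcome))
            elif outcome == "unknown":
                outcome = None
            app = _opt(row.appointment_day)
            att = _opt(row.attended_day)
            patients.append(
                PatientRecord(
                    patient_id=str(row.patient_id),
                    site_id=str(row.site_id),
                    baseline_grade=str(row.baseline_grade),
                    hba1c_percent=_opt(row.hba1c_percent),
                    age_years=_opt(row.age_years),
                    diabetes_duration_years=_opt(row.diabetes_duration_years),
                    insulin_use=str(row.insulin_use) if _opt(row.insulin_use) else "unknown",
                    score_left=_opt(row.score_left),
                    score_right=_opt(row.score_right),
                    appointment_day=None if app is None else int(app),
                    attended_day=None if att is None else int(att),
                    gradable_image=bool(int(row.gradable_image)),
                    outcome_mod_plus=outcome,
                )
            )
        return cls(patients=patients, provenance=provenance)

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        frame = pd.read_csv(path, dtype={"patient_id": str, "site_id": str})
        return cls.from_frame(frame, provenance=str(path))
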