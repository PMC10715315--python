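import numpy as np
import pytest

from screenrank import (
    Cohort,
    PatientRecord,
    count_exact_fixture,
    simulate_cohort,
    table1_config,
)


def make_patient(pid, grade="NO_DR", **kw):
    defaults = dict(
        site_id="s1",
        hba1c_percent=7.0,
        age_years=60.0,
        diabetes_duration_years=8.0,
        insulin_use="no",
        score_left=0.1,
        score_right=0.2,
        appointment_day=365,
        attended_day=365,
        gradable_image=True,
        outcome_mod_plus=False,
    )
    defaults.update(kw)
    return PatientRecord(patient_id=pid, baseline_grade=grade, **defaults)


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic-count cohort with the published per-site integers."""
    return count_exact_fixture(seed=7)


@pytest.fixture(scope="session")
def small_sim_cohort():
    """A small stochastic cohort (single faithful site)."""
    cfg = table1_config(seed=11)
    cfg.sites = cfg.sites[:1]  # khlong_luang, 66 patients
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_cohort():
    """Six patients: 2 mild (1 progressor), 4 no DR (1 progressor)."""
    rows = [
        make_patient("p1", grade="MILD", hba1c_percent=8.0, outcome_mod_plus=True,
                     score_left=0.8, score_right=0.6),
        make_patient("p2", grade="MILD", hba1c_percent=7.0, score_left=0.5, score_right=None),
        make_patient("p3", hba1c_percent=9.5, score_left=0.3, score_right=0.4),
        make_patient("p4", hba1c_percent=6.0, outcome_mod_plus=True,
                     score_left=0.35, score_right=0.1),
        make_patient("p5", hba1c_percent=7.5, score_left=0.05, score_right=0.2),
        make_patient("p6", hba1c_percent=7.5, score_left=0.15, score_right=0.02),
    ]
    return Cohort(patients=rows)
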