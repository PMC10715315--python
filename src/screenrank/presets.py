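"""Calibration presets for the four-site Thai screening cohort.

Two ways to obtain a cohort with the published structure (1757 analyzed
patients across Khlong Luang, Phrao, Rajavithi and San Patong; 179 mild
DR at baseline; 52 MOD+ progressors of whom 23 had mild and 29 no DR):

* :func:`table1_config` — a :class:`~screenrank.simulate.SimConfig` whose
  Bernoulli draws match the published marginals in expectation; use for
  stochastic / replicate studies.
* :func:`count_exact_fixture` — a deterministic-count cohort in which the
  per-site, per-grade patient and progressor counts are fixed to the
  published integers rather than sampled (positions of progressors within
  each grade group randomized by seed), so count arithmetic reproduces
  exactly.  Scores are noise-free by default (sigma_s = 0), which makes
  the model ranking coincide with the true-risk ranking.
"""

from __future__ import annotations


import numpy as np
from scipy.special import expit

from .cohort import Cohort, PatientRecord, MILD, NO_DR
from .simulate import (
    HBA1C_BOUNDS,
    SimConfig,
    SiteProfile,
    calibrate_grade_intercepts,
    _truncated_normal,
)

__all__ = ["table1_sites", "table1_config", "count_exact_fixture", "SITE_POSITIVE_COUNTS"]

# Per-site MOD+ progressor counts (mild-DR progressors, no-DR progressors).
SITE_POSITIVE_COUNTS: dict[str, tuple[int, int]] = {
    "khlong_luang": (2, 0),
    "phrao": (19, 18),
    "rajavithi": (0, 0),
    "san_patong": (2, 11),
}

# Per-site mild-DR counts at baseline.
SITE_MILD_COUNTS: dict[str, int] = {
    "khlong_luang": 21,
    "phrao": 113,
    "rajavithi": 20,
    "san_patong": 25,
}


def table1_sites() -> list[SiteProfile]:
    """The four analyzed sites with published size, grade mix, HbA1c and
    follow-up moments; Phrao is the batched-adherence rural site."""
    return [
        SiteProfile(
            site_id="khlong_luang", n_patients=66, frac_mild_dr=21 / 66,
            hba1c_mean=7.8, hba1c_sd=1.6,
            followup_mean_days=353.1, followup_sd_days=29.4,
            age_mean=60.2, age_sd=11.1, duration_mean=6.8, duration_sd=4.9,
            insulin_freqs=(8 / 66, 56 / 66, 2 / 66),
        ),
        SiteProfile(
            site_id="phrao", n_patients=1190, frac_mild_dr=113 / 1190,
            hba1c_mean=7.3, hba1c_sd=1.8,
            adherence_mode="batched", n_batches=25,
            followup_mean_days=383.5, followup_sd_days=36.5,
            age_mean=58.8, age_sd=8.30, duration_mean=7.2, duration_sd=5.8,
            insulin_freqs=(184 / 1190, 902 / 1190, 104 / 1190),
        ),
        SiteProfile(
            site_id="rajavithi", n_patients=55, frac_mild_dr=20 / 55,
            hba1c_mean=7.9, hba1c_sd=1.6,
            followup_mean_days=359.1, followup_sd_days=42.9,
            age_mean=55.9, age_sd=10.5, duration_mean=9.3, duration_sd=7.6,
            insulin_freqs=(16 / 55, 39 / 55, 0.0),
        ),
        SiteProfile(
            site_id="san_patong", n_patients=446, frac_mild_dr=25 / 446,
            hba1c_mean=7.6, hba1c_sd=1.7,
            followup_mean_days=367.2, followup_sd_days=35.3,
            age_mean=58.6, age_sd=9.01, duration_mean=8.7, duration_sd=5.8,
            insulin_freqs=(12 / 446, 432 / 446, 2 / 446),
        ),
    ]


def table1_config(seed: int = 0, **overrides) -> SimConfig:
    """SimConfig calibrated to the published cohort (1757 patients)."""
    return SimConfig(sites=table1_sites(), seed=seed, **overrides)


def count_exact_fixture(
    seed: int = 0,
    score_noise_sd: float = 0.0,
    hba1c_effect_per_unit: float = 0.15,
    exclude_sites: tuple[str, ...] = (),
) -> Cohort:
    """Build the deterministic-count cohort from the published integers.

    Every site gets exactly its published number of mild-DR and no-DR
    patients, and exactly its published number of MOD+ progressors per
    grade group, placed at seed-randomized positions within the group.
    HbA1c, covariates and schedule are drawn as in the stochastic
    simulator.  Scores are the true logistic risk (plus optional
    logit-scale noise); with the default effect size the grade intercept
    gap dominates the HbA1c term, so all mild-DR patients outrank all
    no-DR patients — matching the published coincidence of the
    grade-based and model rankings at low screened fractions.
    """
    rng = np.random.default_rng(seed)
    sites = [s for s in table1_sites() if s.site_id not in exclude_sites]

    grade_mild_parts, hba1c_parts, outcome_parts = [], [], []
    for site in sites:
        n = site.n_patients
        n_mild = SITE_MILD_COUNTS[site.site_id]
        k_mild, k_nodr = SITE_POSITIVE_COUNTS[site.site_id]
        mild = np.zeros(n, dtype=bool)
        mild[:n_mild] = True
        out = np.zeros(n, dtype=bool)
        out[rng.choice(n_mild, size=k_mild, replace=False)] = True
        out[n_mild + rng.choice(n - n_mild, size=k_nodr, replace=False)] = True
        grade_mild_parts.append(mild)
        outcome_parts.append(out)
        hba1c_parts.append(
            _truncated_normal(rng, site.hba1c_mean, site.hba1c_sd, *HBA1C_BOUNDS, size=n)
        )
    grade_mild = np.concatenate(grade_mild_parts)
    outcome = np.concatenate(outcome_parts)
    hba1c = np.concatenate(hba1c_parts)
    dh = hba1c - hba1c.mean()

    gamma = hba1c_effect_per_unit
    risk = np.empty(grade_mild.size)
    for is_mild, rate in ((False, 29 / 1578), (True, 23 / 179)):
        mask = grade_mild == is_mild
        beta = calibrate_grade_intercepts(rate, dh[mask], gamma)
        risk[mask] = expit(beta + gamma * dh[mask])
    eta = np.log(risk / (1 - risk))
    if score_noise_sd > 0:
        score_l = expit(eta + rng.normal(0, score_noise_sd, risk.size))
        score_r = expit(eta + rng.normal(0, score_noise_sd, risk.size))
    else:
        score_l = score_r = risk

    patients: list[PatientRecord] = []
    i = 0
    width = len(str(grade_mild.size))
    for site in sites:
        n = site.n_patients
        sl = slice(i, i + n)
        best = np.maximum(score_l[sl], score_r[sl])
        order = np.argsort(-best, kind="stable")
        position = np.empty(n)
        position[order] = np.arange(n)
        frac = position / max(n - 1, 1)
        days = np.round(
            site.followup_mean_days + (2 * frac - 1) * site.followup_sd_days
        ).astype(int)
        age = np.clip(rng.normal(site.age_mean, site.age_sd, n), 18, 100)
        dur = np.clip(rng.normal(site.duration_mean, site.duration_sd, n), 0, 60)
        freqs = np.asarray(site.insulin_freqs)
        insulin = rng.choice(["yes", "no", "unknown"], size=n, p=freqs / freqs.sum())
        jitter = np.round(rng.normal(0, 10, n)).astype(int)
        for j in range(n):
            g = i + j
            patients.append(
                PatientRecord(
                    patient_id=f"P{g:0{width}d}",
                    site_id=site.site_id,
                    baseline_grade=MILD if grade_mild[g] else NO_DR,
                    hba1c_percent=float(hba1c[g]),
                    age_years=float(age[j]),
                    diabetes_duration_years=float(dur[j]),
                    insulin_use=str(insulin[j]),
                    score_left=float(score_l[g]),
                    score_right=float(score_r[g]),
                    appointment_day=int(days[j]),
                    attended_day=max(int(days[j] + jitter[j]), 0),
                    gradable_image=True,
                    outcome_mod_plus=bool(outcome[g]),
                )
            )
        i += n
    return Cohort(patients=patients, provenance=f"count_exact_fixture(seed={seed})")
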