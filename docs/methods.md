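# Methods

## Problem and estimand

A screening program recalls N patients for a follow-up visit. K of them
will have progressed to moderate-or-worse (MOD+) diabetic retinopathy by
that visit. Given a proposed recall order, the quantity of interest is
the **sensitivity at fraction screened**,

    S(f) = (# progressors among the first n = ⌊f·N⌋ ranked patients) / K,

and in particular S(0.5): how many progressors are seen in the first half
of the recall schedule. The step function of S over the exact grid
f = k/N, k = 0..N is the capture curve of the ranking. S is undefined
when K = 0 (the package raises `UndefinedSensitivityError`; a cohort in
which nobody progressed has no sensitivity to report).

## Cohort model

The simulator draws, per site:

* baseline grade: mild DR with probability `frac_mild_dr`, else no DR;
* HbA1c ~ Normal(`hba1c_mean`, `hba1c_sd`) truncated to [4, 15]%
  (physiologic plausibility bounds; a plain normal occasionally produces
  impossible values at site SDs near 1.8);
* latent progression risk
  r = logistic(β_grade + γ·(HbA1c − cohort mean HbA1c)),
  outcome ~ Bernoulli(r);
* per-eye scores s = logistic(logit r + Normal(0, σ_s)), drawn
  independently per eye; the patient-level score is the max over eyes.

The grade intercepts β_NO_DR, β_MILD are **calibrated** per draw: for
each grade, β solves mean over that grade's sampled HbA1c of
logistic(β + γ·Δh) = target marginal rate. The mean is strictly
increasing in β, so Brent root-finding on [−20, 20] (xtol 1e-12,
comfortably inside the 1e-10 contract) finds the unique root. With γ = 0
this collapses to β = logit(rate). Calibration makes the realized
marginal progression rates match the configured ones in expectation
regardless of the site mix, which is what the replicate-recovery tests
check.

The logistic grade+HbA1c form is the minimal structure under which the
grade-based (B), HbA1c-based (C) and score-based (D) rankings are all
informative but distinct; the published data constrain only the marginal
rates per grade, not the joint law.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `rate_mod_plus_given_no_dr` | 29/1578 ≈ 0.018 | probability | study marginal |
| `rate_mod_plus_given_mild_dr` | 23/179 ≈ 0.128 | probability | study marginal |
| `hba1c_effect_per_unit` (γ) | 0.15 | log-odds per HbA1c % point | within the epidemiological range (OR ≈ 1.16/point); with the [4, 15] truncation the maximum HbA1c shift (0.15 × 11 = 1.65) stays below the grade intercept gap (logit 0.128 − logit 0.018 ≈ 2.08), so grade dominates the risk order — matching the observed coincidence of the grade-first and model rankings at low screened fractions |
| `score_noise_sd` (σ_s) | 0.5 | logit scale | moderate discrimination; σ_s = 0 makes the score a perfect monotone function of true risk |
| `missing_hba1c_rate` | 0 | probability | the preset describes the analysis-eligible cohort; raise it to exercise the eligibility filter |
| `faithful_swap_prob` | 0.05 | probability per adjacent pair | near-monotone but imperfect adherence at compliant sites |
| `attendance_jitter_sd_days` | 10 | days | no-show/reschedule noise around the appointment |

The four-site preset (`table1_config`) fixes per-site size, grade mix,
HbA1c moments, follow-up-interval moments, age and diabetes-duration
moments, and insulin-use frequencies; the rural high-volume site is
batched (`n_batches = 25` — "numerous" blocks of ~48 patients,
consistent with months of group bus transport) and the other three are
faithful.

### Observed order

`simulate_observed_order` perturbs a proposed order. Faithful mode makes
one left-to-right pass, independently swapping each adjacent pair with
probability `swap_prob` (a swapped pair is skipped, so displacement is at
most one position). Batched mode cuts the proposed order into
`n_batches` contiguous blocks, permutes the block visiting order
uniformly, and permutes patients uniformly within blocks; `n_batches = 1`
and `n_batches = N` both degenerate to a uniform permutation.

### Schedule

The study records appointment and attendance dates but no generative
process, so the simulator assigns appointments by mapping the within-site
model-score order linearly onto `followup_mean ± followup_sd` days, and
sets attendance = appointment + rounded Normal(0, 10), floored at 0.
This exists to exercise the eligibility filters, not to model clinic
logistics.

### What the generator does not emulate

Real per-patient model scores (the simulator's scores derive from the
same logistic risk that generates outcomes, so score discrimination is a
knob, not an empirical fact); DR grade transitions beyond the binary
MOD+ endpoint; correlation between eyes beyond shared true risk;
covariate–risk association for age/duration/insulin (defaults to none,
so covariate rankings are uninformative beyond grade on simulated data);
seasonal or capacity effects in scheduling. Consequently, passing tests
validate the *pipeline arithmetic and inference*, not the real-world
performance of any particular risk model.

## Eligibility

A patient is analysis-eligible iff they attended, attended ≥ 150 days
after baseline, attended within ±60 days of the appointment (boundaries:
exactly 150 and a gap of exactly 60 are eligible — "within" read
inclusively, "<150" exclusively), and have HbA1c, a gradable image, and
a known outcome (each requirement toggleable). Excluded patients are
logged under the **first** failing rule in the fixed order no_followup →
attended_early → outside_window → missing_hba1c → ungradable_image →
unknown_outcome, so reasons partition the exclusions. An attendance with
no appointment on record cannot satisfy the window rule and falls under
outside_window.

## Rankings

Deterministic sorts (C, D, covariate age/duration, E) break exact ties by
patient_id so they are fully reproducible; randomized strategies (A, B,
insulin levels, grade_only) take a seed. Covariate directions: older
first, longer duration first, insulin users first — the clinical-risk
direction. The cross-site merge keys each patient by the normalized
within-site rank (position − 0.5)/site_size and sorts ascending (ties:
larger site first, then patient_id); this is the canonical
order-preserving proportional interleave and keeps every site's internal
prioritization intact as a subsequence.

## Capture curves and closed forms

n at fraction f is ⌊f·N⌋ with a +1e-9 nudge before the floor: fractions
supplied as exact ratios k/N must recover n = k, and binary floating
point can make (179/1757)·1757 fractionally less than 179. With N = 1757
and f = 0.5 this gives n = 878 (round-half-up would give 879 and shift
the half-screened expectation from 68.9% to 69.0%).

For the grade-first random ranking the expectation is closed-form: the
first min(n, m) screens draw uniformly from the m mild patients (K_m
progressors), the remainder from the N − m no-DR patients (K_n), so

    E[S(f)] = (K_m·n/m)/K                      if n ≤ m
            = (K_m + K_n·(n−m)/(N−m))/K        if n > m.

For the uniform random ranking the captured count is
Hypergeometric(N, K, n) with mean n·K/N, hence E[S] = n/N. Both closed
forms serve as oracles for the Monte-Carlo averaging path.

## Inference

Permutation test: the observed ranking is held fixed; each of B
iterations re-orders the cohort under the null strategy (uniform, or
uniform within grade blocks with the mild block first) and records the
null S at the same fraction. p = (1 + #{S_null ≥ S_obs})/(1 + B) — never
zero, conservative on the discrete null; "≥" (not ">") keeps it
conservative. The ≥-comparison uses a 1e-12 tolerance so equal
sensitivities computed by different code paths count as ties. Null draws
are generated by permuting the outcome labels (vectorized,
`Generator.permuted` row-wise), which is distribution-identical to
re-ranking the patients. Under the uniform null the captured count is
exactly Hypergeometric(N, K, n); `hypergeometric_tail` computes P[X ≥ k]
by log-space summation of the pmf (gammaln + logsumexp), giving an
analytic cross-check of any permutation p-value.

Mann–Whitney: list positions are the rank variable (ties impossible by
construction), alternative "progressor positions are smaller". Exact
enumeration when n₊·n₋ ≤ 10,000, else the normal approximation with
continuity correction; the cutoff balances exactness against runtime,
and the two methods agree to < 0.01 in the regimes the tests probe.

## The deterministic-count cohort

`count_exact_fixture` builds the four-site cohort with the per-site,
per-grade patient and progressor counts fixed to the study integers
(progressor positions within each grade group randomized by seed), so
count arithmetic — overall 52/1757, mild share 179/1757, per-grade rates,
the 567-patient three-site subset with 15 progressors — is exact rather
than stochastic. Scores are noise-free by default, so the model ranking
coincides with the true-risk ranking and, because grade dominates risk
(see γ above), places the whole mild block first.

## Problem sizes and numerical choices

Default test and reproduction sizes: 10,000 permutation iterations and
10,000 tie-randomization runs for headline numbers; 500 replicate
cohorts for marginal-rate recovery; 400 replicates at B = 200–300 for
type-I calibration; Kolmogorov distance of the 10,000-draw permutation
null against the exact hypergeometric CDF bounded at 0.02. Monte-Carlo
comparisons use 3 empirical standard errors. Seeds for sub-streams are
spawned via `numpy.random.SeedSequence` and kept below 2³¹.

## Known limitations

* The cross-site combination rule is the package's own normalized-rank
  merge; other order-preserving merges (e.g. capacity-weighted) are
  plausible and not implemented.
* The permutation test conditions on the observed ranking and
  re-randomizes only the null comparator; it does not re-randomize the
  tested strategy's own tie-breaking per iteration.
* No multiple-testing correction across strategy comparisons, and no AUC
  summary of capture curves.
* Sensitivity is reported at exact grid fractions only; figure-style
  interpolation is left to plotting code.
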