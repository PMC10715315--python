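import numpy as np
import pytest
from scipy.stats import hypergeom

from screenrank import (
    Cohort,
    InferenceConfig,
    hypergeometric_tail,
    mann_whitney_ranks,
    permutation_test,
    rank_random,
)
from screenrank.capture import UndefinedSensitivityError
from screenrank.ranking import RankedList

from conftest import make_patient


def _cohort_with_positives(n, k):
    return Cohort(patients=[
        make_patient(f"p{i}", outcome_mod_plus=(i < k)) for i in range(n)
    ])


class TestHypergeometricTail:
    def test_zero_threshold_is_certain(self):
        assert hypergeometric_tail(50, 10, 20, 0) == 1.0

    def test_small_case_binomial_coefficient_arithmetic(self):
        # C(10,5)*C(10,0)/C(20,5) = 252/15504
        assert hypergeometric_tail(20, 5, 10, 5) == pytest.approx(252 / 15504, rel=1e-12)

    def test_published_scale_tail_is_below_alpha(self):
        assert hypergeometric_tail(1757, 52, 878, 47) < 1e-3

    @pytest.mark.parametrize("n_total,k_pop,n_draw", [(20, 5, 10), (100, 13, 37), (1757, 52, 878)])
    def test_agrees_with_scipy_over_support(self, n_total, k_pop, n_draw):
        for k in range(1, min(k_pop, n_draw) + 1, max(1, k_pop // 7)):
            mine = hypergeometric_tail(n_total, k_pop, n_draw, k)
            ref = hypergeom.sf(k - 1, n_total, k_pop, n_draw)
            assert mine == pytest.approx(ref, rel=1e-9, abs=1e-300)

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(10, 11, 5, 1)
        with pytest.raises(ValueError):
            hypergeometric_tail(10, 5, 5, 6)


class TestPermutationTest:
    def test_point_mass_oracle(self):
        # N=20, K=5, all progressors first: only a null draw capturing all
        # five in the first ten ties the observed statistic
        cohort = _cohort_with_positives(20, 5)
        ranked = RankedList("D_model", cohort.patient_ids)
        res = permutation_test(ranked, cohort.outcomes(), cohort,
                               InferenceConfig(n_permutations=10_000, seed=0))
        exact = 252 / 15504
        se = np.sqrt(exact * (1 - exact) / 10_000)
        assert res.observed_sensitivity == 1.0
        assert abs(res.p_value - exact) < 3 * se

    def test_minimal_statistic_gives_p_one(self):
        cohort = _cohort_with_positives(20, 3)
        worst = RankedList("D_model", cohort.patient_ids[3:] + cohort.patient_ids[:3])
        res = permutation_test(worst, cohort.outcomes(), cohort,
                               InferenceConfig(n_permutations=200, seed=1))
        assert res.observed_sensitivity == 0.0
        assert res.p_value == 1.0

    def test_add_one_estimator_bounds(self):
        cohort = _cohort_with_positives(10, 2)
        ranked = RankedList("D_model", cohort.patient_ids)
        for n_perm in (1, 37):
            res = permutation_test(ranked, cohort.outcomes(), cohort,
                                   InferenceConfig(n_permutations=n_perm, seed=2))
            assert 1 / (n_perm + 1) <= res.p_value <= 1.0

    def test_grade_blocked_null_respects_blocks(self):
        # 4 mild (2 progressors) + 16 no DR (0 progressors), f=0.2 screens
        # exactly the mild block, so every grade-blocked draw captures both
        # progressors and the null is degenerate at sensitivity 1
        patients = [make_patient(f"m{i}", grade="MILD", outcome_mod_plus=i < 2)
                    for i in range(4)]
        patients += [make_patient(f"n{i}") for i in range(16)]
        cohort = Cohort(patients=patients)
        ranked = RankedList("C_grade_hba1c", cohort.patient_ids)
        res = permutation_test(ranked, cohort.outcomes(), cohort,
                               InferenceConfig(n_permutations=500, fraction=0.2, seed=3),
                               null_strategy="B_grade_random")
        assert np.all(res.null_draws == 1.0)
        assert res.p_value == 1.0

    def test_no_progressors_is_undefined(self):
        cohort = _cohort_with_positives(10, 0)
        ranked = RankedList("A_random", cohort.patient_ids)
        with pytest.raises(UndefinedSensitivityError):
            permutation_test(ranked, cohort.outcomes(), cohort)

    def test_seed_determinism(self):
        cohort = _cohort_with_positives(30, 6)
        ranked = rank_random(cohort, seed=4)
        cfg = InferenceConfig(n_permutations=300, seed=9)
        a = permutation_test(ranked, cohort.outcomes(), cohort, cfg)
        b = permutation_test(ranked, cohort.outcomes(), cohort, cfg)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null_draws, b.null_draws)

    def test_null_ecdf_matches_exact_hypergeometric_cdf(self):
        # the uniform null of captured-count is Hypergeometric(N, K, n)
        n_total, k_pop, n_draws = 200, 20, 10_000
        cohort = _cohort_with_positives(n_total, k_pop)
        ranked = rank_random(cohort, seed=5)
        res = permutation_test(ranked, cohort.outcomes(), cohort,
                               InferenceConfig(n_permutations=n_draws, seed=6))
        counts = np.round(res.null_draws * k_pop).astype(int)
        n_half = n_total // 2
        ks = 0.0
        for k in range(k_pop + 1):
            ecdf = np.mean(counts <= k)
            cdf = 1.0 - (hypergeometric_tail(n_total, k_pop, n_half, k + 1)
                         if k + 1 <= min(k_pop, n_half) else 0.0)
            ks = max(ks, abs(ecdf - cdf))
        assert ks < 0.02

    def test_type_one_error_calibration_under_null(self):
        # a random ranking tested against the random null: valid, close to
        # nominal but conservative on the discrete statistic grid
        n_total, k_pop, reps, n_perm = 200, 20, 400, 300
        cohort = _cohort_with_positives(n_total, k_pop)
        outcomes = cohort.outcomes()
        rng = np.random.default_rng(7)
        pvals = []
        for r in range(reps):
            ranked = rank_random(cohort, int(rng.integers(2**31)))
            res = permutation_test(ranked, outcomes, cohort,
                                   InferenceConfig(n_permutations=n_perm,
                                                   seed=int(rng.integers(2**31))))
            pvals.append(res.p_value)
        pvals = np.asarray(pvals)
        rate = np.mean(pvals <= 0.05)
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rate <= 0.05 + 3 * se
        assert rate >= 0.01
        assert 0.45 <= pvals.mean() <= 0.62

    def test_perfect_discrimination_has_high_power(self):
        # noise-free scores that separate progressors exactly: the model
        # order captures all K in the first K slots and the test rejects
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 20
        for r in range(reps):
            n_total, k_pop = 300, 24
            flags = np.zeros(n_total, dtype=bool)
            flags[rng.choice(n_total, k_pop, replace=False)] = True
            cohort = Cohort(patients=[
                make_patient(f"p{i}", outcome_mod_plus=bool(flags[i]),
                             score_left=0.9 if flags[i] else 0.1,
                             score_right=0.9 if flags[i] else 0.1)
                for i in range(n_total)
            ])
            from screenrank import rank_model

            res = permutation_test(rank_model(cohort), cohort.outcomes(), cohort,
                                   InferenceConfig(n_permutations=200,
                                                   seed=int(rng.integers(2**31))))
            rejections += res.p_value <= 0.05
        assert rejections / reps > 0.95


class TestMannWhitney:
    def test_positives_first_small_exact(self):
        # N=6, K=2, progressors in the first two slots: p = 1/C(6,2)
        cohort = _cohort_with_positives(6, 2)
        ranked = RankedList("D_model", cohort.patient_ids)
        res = mann_whitney_ranks(ranked, cohort.outcomes())
        assert res.method == "exact"
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(1 / 15)

    def test_even_interleaving_is_null_consistent(self):
        ids = [f"p{i}" for i in range(40)]
        outcomes = {pid: i % 2 == 0 for i, pid in enumerate(ids)}
        res = mann_whitney_ranks(RankedList("D_model", ids), outcomes)
        assert 0.3 < res.p_value < 0.7

    def test_u_statistic_bounds(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            cohort = _cohort_with_positives(25, 6)
            ranked = rank_random(cohort, int(rng.integers(2**31)))
            res = mann_whitney_ranks(ranked, cohort.outcomes())
            assert 0 <= res.u_statistic <= res.n_positive * res.n_negative

    def test_normal_approximation_tracks_exact_enumeration(self):
        rng = np.random.default_rng(11)
        cohort = _cohort_with_positives(30, 5)
        outcomes = cohort.outcomes()
        for _ in range(25):
            ranked = rank_random(cohort, int(rng.integers(2**31)))
            exact = mann_whitney_ranks(ranked, outcomes, method="exact")
            approx = mann_whitney_ranks(ranked, outcomes, method="asymptotic")
            assert abs(exact.p_value - approx.p_value) < 0.01

    def test_large_cohort_switches_to_asymptotic(self, fixture_cohort):
        from screenrank import rank_model

        res = mann_whitney_ranks(rank_model(fixture_cohort), fixture_cohort.outcomes())
        assert res.method == "asymptotic"
        assert res.p_value < 0.05  # grade-dominant risk order beats chance

    def test_degenerate_groups_rejected(self):
        cohort = _cohort_with_positives(5, 0)
        ranked = RankedList("D_model", cohort.patient_ids)
        with pytest.raises(ValueError, match="at least one"):
            mann_whitney_ranks(ranked, cohort.outcomes())
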