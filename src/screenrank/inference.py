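"""Statistical tests on ranked screening orders.

Superiority of a ranking's sensitivity at a fixed screened fraction is
tested against two permutation nulls — uniform random re-ordering
(approach A) and grade-blocked random re-ordering (approach B) — with the
add-one p-value estimator p = (1 + #{null >= observed}) / (1 + B), which
is never zero and is conservative on the discrete null.  The uniform
null has an exact counterpart: the count of progressors captured in the
first n of N positions is Hypergeometric(N, K, n), whose upper tail is
computed here in log space as an independent cross-check.  A one-sided
Mann-Whitney U test asks whether progressors occupy earlier list
positions than non-progressors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import mannwhitneyu

from .capture import UndefinedSensitivityError, n_screened, sensitivity_at_fraction
from .cohort import Cohort, MILD
from .ranking import RankedList

__all__ = [
    "InferenceConfig",
    "PermutationTestResult",
    "RankTestResult",
    "permutation_test",
    "hypergeometric_tail",
    "mann_whitney_ranks",
]

EXACT_MW_CUTOFF = 10_000  # exact enumeration when n_pos * n_neg is at most this


@dataclass
class InferenceConfig:
    n_permutations: int = 10_000
    fraction: float = 0.5
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must lie in (0, 1]")


@dataclass
class PermutationTestResult:
    observed_sensitivity: float
    null_strategy: str
    null_draws: np.ndarray
    p_value: float
    n_permutations: int
    fraction: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "null_strategy": self.null_strategy,
            "observed_sensitivity": self.observed_sensitivity,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "fraction": self.fraction,
            "seed": self.seed,
        }


@dataclass
class RankTestResult:
    u_statistic: float
    p_value: float
    n_positive: int
    n_negative: int
    method: str  # "exact" or "asymptotic"
    tie_corrected: bool = False


def _null_draws_uniform(rng, pos: np.ndarray, n: int, n_draws: int) -> np.ndarray:
    """Sensitivities of uniform random re-orderings: permute the outcome
    labels and count progressors in the first n slots (vectorized)."""
    k_total = int(pos.sum())
    mat = np.tile(pos, (n_draws, 1))
    rng.permuted(mat, axis=1, out=mat)
    return mat[:, :n].sum(axis=1) / k_total


def _null_draws_grade_blocked(
    rng, pos_mild: np.ndarray, pos_nodr: np.ndarray, n: int, n_draws: int
) -> np.ndarray:
    """Sensitivities of grade-blocked re-orderings: the mild block fills
    the first m positions, so independently permute outcomes within each
    block and count captures in the first n."""
    m = pos_mild.size
    k_total = int(pos_mild.sum() + pos_nodr.sum())
    captured = np.zeros(n_draws)
    n_mild_screened = min(n, m)
    if n_mild_screened > 0 and m > 0:
        mat = np.tile(pos_mild, (n_draws, 1))
        rng.permuted(mat, axis=1, out=mat)
        captured += mat[:, :n_mild_screened].sum(axis=1)
    n_nodr_screened = max(0, n - m)
    if n_nodr_screened > 0 and pos_nodr.size > 0:
        mat = np.tile(pos_nodr, (n_draws, 1))
        rng.permuted(mat, axis=1, out=mat)
        captured += mat[:, :n_nodr_screened].sum(axis=1)
    return captured / k_total


def permutation_test(
    ranked: RankedList,
    outcomes: Mapping[str, bool],
    cohort: Cohort,
    config: Optional[InferenceConfig] = None,
    null_strategy: str = "A_random",
) -> PermutationTestResult:
    """One-sided permutation superiority test of sensitivity at a fraction.

    The observed ranking is held fixed; each of B iterations re-ranks the
    cohort under the null strategy (A: uniform; B: all mild DR first,
    random within grade blocks) and records the null sensitivity at the
    same fraction.  p = (1 + #{null >= observed}) / (1 + B).
    """
    config = config or InferenceConfig()
    observed = sensitivity_at_fraction(ranked, outcomes, config.fraction)
    n = n_screened(config.fraction, len(ranked))
    rng = np.random.default_rng(config.seed)

    if null_strategy == "A_random":
        pos = np.fromiter(
            (outcomes[p.patient_id] for p in cohort), dtype=bool, count=len(cohort)
        )
        draws = _null_draws_uniform(rng, pos, n, config.n_permutations)
    elif null_strategy == "B_grade_random":
        pos_mild = np.array(
            [outcomes[p.patient_id] for p in cohort if p.baseline_grade == MILD], dtype=bool
        )
        pos_nodr = np.array(
            [outcomes[p.patient_id] for p in cohort if p.baseline_grade != MILD], dtype=bool
        )
        draws = _null_draws_grade_blocked(rng, pos_mild, pos_nodr, n, config.n_permutations)
    else:
        raise ValueError("null_strategy must be 'A_random' or 'B_grade_random'")

    exceed = int(np.sum(draws >= observed - 1e-12))
    p_value = (1 + exceed) / (1 + config.n_permutations)
    return PermutationTestResult(
        observed_sensitivity=observed,
        null_strategy=null_strategy,
        null_draws=draws,
        p_value=p_value,
        n_permutations=config.n_permutations,
        fraction=config.fraction,
        seed=config.seed,
    )


def _log_hypergeom_pmf(x: np.ndarray, n_total: int, k_pop: int, n_draw: int) -> np.ndarray:
    return (
        gammaln(k_pop + 1)
        - gammaln(x + 1)
        - gammaln(k_pop - x + 1)
        + gammaln(n_total - k_pop + 1)
        - gammaln(n_draw - x + 1)
        - gammaln(n_total - k_pop - (n_draw - x) + 1)
        - (gammaln(n_total + 1) - gammaln(n_draw + 1) - gammaln(n_total - n_draw + 1))
    )


def hypergeometric_tail(n_total: int, k_pop: int, n_draw: int, k: int) -> float:
    """Exact P[X >= k] for X ~ Hypergeometric(N, K, n), in log space.

    The exact null distribution of the number of progressors captured in
    the first n positions of a uniformly random ordering.
    """
    if not (0 <= k_pop <= n_total and 0 <= n_draw <= n_total):
        raise ValueError("require 0 <= K, n <= N")
    if not 0 <= k <= min(k_pop, n_draw):
        raise ValueError("require 0 <= k <= min(K, n)")
    if k == 0:
        return 1.0
    lo = max(k, k_pop + n_draw - n_total)
    x = np.arange(lo, min(k_pop, n_draw) + 1)
    return float(np.exp(logsumexp(_log_hypergeom_pmf(x, n_total, k_pop, n_draw))))


def mann_whitney_ranks(
    ranked: RankedList, outcomes: Mapping[str, bool], method: Optional[str] = None
) -> RankTestResult:
    """One-sided Mann-Whitney U: do progressors occupy earlier positions?

    List positions are the rank variable, so ties are impossible by
    construction.  Exact enumeration is used when n_pos * n_neg <= 10,000,
    otherwise the normal approximation with continuity correction;
    ``method`` ("exact" / "asymptotic") overrides the automatic choice.
    """
    positions = np.arange(1, len(ranked) + 1)
    pos_mask = np.fromiter(
        (outcomes[pid] for pid in ranked.order), dtype=bool, count=len(ranked)
    )
    x = positions[pos_mask]
    y = positions[~pos_mask]
    if x.size == 0 or y.size == 0:
        raise ValueError("need at least one progressor and one non-progressor")
    if method is None:
        method = "exact" if x.size * y.size <= EXACT_MW_CUTOFF else "asymptotic"
    res = mannwhitneyu(x, y, alternative="less", method=method, use_continuity=True)
    return RankTestResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_positive=int(x.size),
        n_negative=int(y.size),
        method=method,
    )
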