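"""Sensitivity-versus-fraction-screened capture curves.

For a ranked screening list over N patients of whom K progress to MOD+,
the sensitivity at fraction f is the share of the K progressors found
among the first n = floor(f*N) patients.  Sweeping f over the exact grid
k/N, k = 0..N yields a monotone step curve from 0 to 1 — the capture
(cumulative accuracy / lift) curve of the ranking.  For strategies with
randomized tie-breaking, curves are averaged over independent
randomization runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from .cohort import Cohort
from .ranking import RankedList

__all__ = [
    "UndefinedSensitivityError",
    "CaptureCurve",
    "n_screened",
    "sensitivity_at_fraction",
    "capture_curve",
    "averaged_curve",
    "expected_sensitivity_grade_first",
]


class UndefinedSensitivityError(ZeroDivisionError):
    """Raised when a cohort has no progressors, so sensitivity has no
    denominator (as at a site where no patients progressed)."""


def n_screened(f: float, n_total: int) -> int:
    """Number screened at fraction f: floor(f * N).

    A 1e-9 nudge absorbs binary-float error so that fractions supplied as
    exact ratios k/N recover n = k (e.g. f = 179/1757 on N = 1757 must
    give 179, not 178).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return int(np.floor(f * n_total + 1e-9))


def _positive_indicator(ranked: RankedList, outcomes: Mapping[str, bool]) -> np.ndarray:
    missing = [pid for pid in ranked.order if pid not in outcomes]
    if missing:
        raise ValueError(f"outcomes missing for ranked patients: {missing[:5]}")
    return np.fromiter((outcomes[pid] for pid in ranked.order), dtype=bool, count=len(ranked))


def sensitivity_at_fraction(
    ranked: RankedList, outcomes: Mapping[str, bool], f: float
) -> float:
    """Fraction of all progressors captured in the first floor(f*N) positions."""
    pos = _positive_indicator(ranked, outcomes)
    k_total = int(pos.sum())
    if k_total == 0:
        raise UndefinedSensitivityError("no progressors in cohort; sensitivity undefined")
    n = n_screened(f, pos.size)
    return float(pos[:n].sum() / k_total)


@dataclass
class CaptureCurve:
    """Step curve of sensitivity on the exact grid k/N, k = 0..N."""

    n_total: int
    n_positive: int
    fractions: np.ndarray
    sensitivities: np.ndarray
    n_runs: int = 1
    per_run_sensitivities: Optional[np.ndarray] = None  # runs x (N+1)

    def at_fraction(self, f: float) -> float:
        return float(self.sensitivities[n_screened(f, self.n_total)])

    def to_frame(self) -> pd.DataFrame:
        data = {"fraction": self.fractions, "sensitivity_mean": self.sensitivities}
        if self.per_run_sensitivities is not None:
            for i, run in enumerate(self.per_run_sensitivities):
                data[f"sensitivity_run_{i}"] = run
        return pd.DataFrame(data)


def capture_curve(ranked: RankedList, outcomes: Mapping[str, bool]) -> CaptureCurve:
    """The exact capture curve of one ranked list."""
    pos = _positive_indicator(ranked, outcomes)
    k_total = int(pos.sum())
    if k_total == 0:
        raise UndefinedSensitivityError("no progressors in cohort; sensitivity undefined")
    n = pos.size
    cum = np.concatenate([[0], np.cumsum(pos)]) / k_total
    return CaptureCurve(
        n_total=n,
        n_positive=k_total,
        fractions=np.arange(n + 1) / n,
        sensitivities=cum,
    )


def averaged_curve(
    strategy_fn: Callable[[Cohort, int], RankedList],
    cohort: Cohort,
    outcomes: Mapping[str, bool],
    n_runs: int = 100,
    seed: int = 0,
) -> CaptureCurve:
    """Mean capture curve over independent tie-randomization runs.

    ``strategy_fn(cohort, run_seed)`` must return a RankedList; run seeds
    are spawned deterministically from ``seed``.  Per-run curves are
    retained for plotting the randomization envelope.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    runs = []
    for i in range(n_runs):
        ranked = strategy_fn(cohort, int(run_seeds[i]))
        runs.append(capture_curve(ranked, outcomes).sensitivities)
    per_run = np.vstack(runs)
    first = capture_curve(strategy_fn(cohort, int(run_seeds[0])), outcomes)
    return CaptureCurve(
        n_total=first.n_total,
        n_positive=first.n_positive,
        fractions=first.fractions,
        sensitivities=per_run.mean(axis=0),
        n_runs=n_runs,
        per_run_sensitivities=per_run,
    )


def expected_sensitivity_grade_first(
    n_total: int, n_mild: int, k_mild: int, k_nodr: int, f: float
) -> float:
    """Closed-form expected sensitivity of the grade-first random ranking.

    All n_mild mild-DR patients (k_mild progressors) precede the no-DR
    block (k_nodr progressors); within blocks the order is uniformly
    random, so the expected count captured in the first n positions is
    linear within each block:

        n <= m:  E[S] = (k_mild * n/m) / K
        n >  m:  E[S] = (k_mild + k_nodr * (n-m)/(N-m)) / K

    with n = floor(f*N), m = n_mild, K = k_mild + k_nodr.
    """
    if not (n_mild <= n_total and k_mild <= n_mild and k_nodr <= n_total - n_mild):
        raise ValueError("inconsistent counts")
    k_total = k_mild + k_nodr
    if k_total == 0:
        raise UndefinedSensitivityError("no progressors; expectation undefined")
    n = n_screened(f, n_total)
    if n <= n_mild:
        captured = k_mild * n / n_mild if n_mild else 0.0
    else:
        captured = k_mild + k_nodr * (n - n_mild) / (n_total - n_mild)
    return captured / k_total
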