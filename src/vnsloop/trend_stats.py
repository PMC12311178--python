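"""Mann-Kendall trend test and cohort outcome summaries.

The closed-loop outcome claim is a *downward trend* in the per-epoch
percent-HR-drop magnitudes: the controller should make successive
stimulation responses smaller.  The Mann-Kendall statistic

    S = sum_{i<j} sign(x_j - x_i)

is tested against the one-sided alternative of a downward trend (H_A:
later values tend to be smaller), rejecting H_0 when S < 0 and p < alpha.

For the short sequences produced by a run (n ~ 5-10) the normal
approximation is rough, so an exact permutation null is used where
feasible: full enumeration of the n! orderings for n <= 8 (valid with
ties), an inversion-count recursion for tie-free n <= 10.  Otherwise the
classical normal approximation with tie-corrected variance and +/-1
continuity correction applies.  Both p-values are reported when available.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .loop import RunRecord

__all__ = [
    "TrendResult",
    "RunSummary",
    "CohortSummary",
    "mann_kendall",
    "run_summary",
    "cohort_summary",
]

_EXACT_BRUTE_N = 8
_EXACT_DP_N = 10


@dataclass
class TrendResult:
    S: int
    var_s: float
    z: float
    p_one_sided_down: float
    p_normal: float
    p_exact: float | None
    n: int
    alpha: float
    significant: bool  # S < 0 and p < alpha (downward alternative)


def _s_statistic(x: np.ndarray) -> int:
    s = 0
    for i in range(len(x) - 1):
        s += int(np.sum(np.sign(x[i + 1 :] - x[i])))
    return s


def _tie_corrected_var(x: np.ndarray) -> float:
    n = len(x)
    var = n * (n - 1) * (2 * n + 5)
    _, counts = np.unique(x, return_counts=True)
    for t in counts[counts > 1]:
        var -= t * (t - 1) * (2 * t + 5)
    return var / 18.0


def _exact_p_brute(x: np.ndarray, s_obs: int) -> float:
    """P(S <= s_obs) under uniform permutation of the observed values."""
    n = len(x)
    count = 0
    total = math.factorial(n)
    for perm in itertools.permutations(x):
        if _s_statistic(np.array(perm)) <= s_obs:
            count += 1
    return count / total


def _inversion_counts(n: int) -> np.ndarray:
    """counts[k] = number of permutations of n items with k inversions."""
    poly = np.array([1.0])
    for m in range(1, n + 1):
        poly = np.convolve(poly, np.ones(m))
    return poly


def _exact_p_dp(n: int, s_obs: int) -> float:
    """Tie-free exact P(S <= s_obs): S = T - 2*inversions, T = n(n-1)/2."""
    T = n * (n - 1) // 2
    counts = _inversion_counts(n)
    ks = np.arange(len(counts))
    s_vals = T - 2 * ks
    return float(counts[s_vals <= s_obs].sum() / math.factorial(n))


def mann_kendall(x, alpha: float = 0.05, exact: str = "auto") -> TrendResult:
    """Mann-Kendall trend test, one-sided downward alternative.

    ``exact``: "auto" (exact null when feasible), "never", or "always"
    (raises if infeasible).  The primary ``p_one_sided_down`` is the exact
    p when computed, otherwise the continuity-corrected normal p.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Mann-Kendall needs at least 3 observations")
    s = _s_statistic(x)
    var = _tie_corrected_var(x)

    if var > 0:
        # reported statistic: the usual sign-dependent continuity correction
        if s > 0:
            z = (s - 1) / math.sqrt(var)
        elif s < 0:
            z = (s + 1) / math.sqrt(var)
        else:
            z = 0.0
        # downward alternative: lower tail P(S <= s_obs), corrected upward
        p_normal = float(stats.norm.cdf((s + 1) / math.sqrt(var)))
    else:  # constant sequence: no evidence of trend
        z = 0.0
        p_normal = 1.0

    p_exact: float | None = None
    has_ties = len(np.unique(x)) < n
    if exact != "never":
        if n <= _EXACT_BRUTE_N:
            p_exact = _exact_p_brute(x, s)
        elif n <= _EXACT_DP_N and not has_ties:
            p_exact = _exact_p_dp(n, s)
        elif exact == "always":
            raise ValueError(f"exact enumeration infeasible for n={n} with ties={has_ties}")

    p = p_exact if p_exact is not None else p_normal
    return TrendResult(
        S=s,
        var_s=var,
        z=z,
        p_one_sided_down=p,
        p_normal=p_normal,
        p_exact=p_exact,
        n=n,
        alpha=alpha,
        significant=bool(s < 0 and p < alpha),
    )


@dataclass
class RunSummary:
    first_drop: float
    last_drop: float
    n_epochs: int
    status: str
    trend: TrendResult | None  # None when fewer than 3 stimulated epochs


def run_summary(record: RunRecord, alpha: float = 0.05) -> RunSummary:
    """Per-run outcome: first/last drop and the trend of drop magnitudes.

    Drop magnitudes are the per-epoch responses clipped at 0 (the tested
    quantity is the magnitude of the percent drop), taken in epoch order.
    """
    drops = np.clip(
        [e.drop for e in record.epochs if np.isfinite(e.drop)], 0.0, None
    )
    trend = mann_kendall(drops, alpha) if len(drops) >= 3 else None
    return RunSummary(
        first_drop=float(drops[0]),
        last_drop=float(drops[-1]),
        n_epochs=len(drops),
        status=record.status,
        trend=trend,
    )


@dataclass
class CohortSummary:
    n_runs: int
    n_S_negative: int
    n_significant: int
    mean_first_drop: float
    mean_last_drop: float
    drop_ratio: float  # mean_first_drop / mean_last_drop
    n_excluded: int  # runs with no usable drop sequence


def cohort_summary(records: list[RunRecord], alpha: float = 0.05) -> CohortSummary:
    """Cohort-level outcome across runs: trend counts and first/last means."""
    if not records:
        raise ValueError("cohort_summary needs at least one run")
    firsts, lasts = [], []
    n_neg = n_sig = n_excl = 0
    for rec in records:
        try:
            summ = run_summary(rec, alpha)
        except (IndexError, ValueError):
            n_excl += 1
            continue
        firsts.append(summ.first_drop)
        lasts.append(summ.last_drop)
        if summ.trend is not None:
            if summ.trend.S < 0:
                n_neg += 1
            if summ.trend.significant:
                n_sig += 1
    mean_first = float(np.mean(firsts)) if firsts else float("nan")
    mean_last = float(np.mean(lasts)) if lasts else float("nan")
    ratio = mean_first / mean_last if mean_last and mean_last > 0 else float("nan")
    return CohortSummary(
        n_runs=len(records),
        n_S_negative=n_neg,
        n_significant=n_sig,
        mean_first_drop=mean_first,
        mean_last_drop=mean_last,
        drop_ratio=ratio,
        n_excluded=n_excl,
    )
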