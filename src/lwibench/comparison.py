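"""Pairwise multiple comparison of methods' bias samples (DTK) and win sums.

At each missingness proportion the methods with a defined GAB are compared
pairwise with the Dunnett modified Tukey-Kramer (DTK, "Dunnett C") procedure
at a family significance level alpha: for methods A and B with MAB samples
of sizes n_A, n_B, means xbar, variances s^2, the confidence interval for
mean(A) - mean(B) has half-width

    q(alpha, J, nu_AB) / sqrt(2) * sqrt(s_A^2/n_A + s_B^2/n_B)

with q the studentized-range quantile for J compared methods and nu_AB the
Welch-Satterthwaite degrees of freedom.  A "wins" the pair when the CI lies
entirely below zero (statistically smaller mean bias).  A method's win
count at a proportion, summed over proportion ranges, reproduces the
benchmark's summary table; the superior set at a proportion is the set of
methods attaining the maximum win count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import studentized_range

__all__ = ["ComparisonOutcome", "dtk_pairwise", "sum_wins", "DEFAULT_RANGES"]

DEFAULT_RANGES: tuple[tuple[int, int], ...] = ((1, 30), (31, 60), (61, 80))


@dataclass
class ComparisonOutcome:
    """Per-proportion win counts and the superior method set."""

    p: int
    wins: dict[str, int]
    superior_set: tuple[str, ...]
    intervals: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict, repr=False
    )


def _welch_df(s2a: float, na: int, s2b: float, nb: int) -> float:
    va, vb = s2a / na, s2b / nb
    denom = va**2 / (na - 1) + vb**2 / (nb - 1)
    if denom <= 0:
        # zero-variance degenerate pair: use the pooled classical df
        return float(na + nb - 2)
    return (va + vb) ** 2 / denom


def dtk_pairwise(
    mab_samples: dict[str, np.ndarray], alpha: float = 0.05, p: int = 0
) -> ComparisonOutcome:
    """DTK pairwise comparison over all methods' MAB samples at one p.

    Only methods present in ``mab_samples`` are compared (methods with a
    failed/undefined GAB are excluded before the call, which also sets the
    family size J for the studentized-range quantile).
    """
    methods = sorted(mab_samples)
    J = len(methods)
    if J < 2:
        raise ValueError("need at least 2 methods to compare")
    stats_ = {}
    for name in methods:
        x = np.asarray(mab_samples[name], dtype=float)
        if len(x) < 2:
            raise ValueError(f"{name}: sample size must be >= 2")
        stats_[name] = (x.mean(), x.var(ddof=1), len(x))

    wins = {name: 0 for name in methods}
    intervals = {}
    for a, b in combinations(methods, 2):
        ma, s2a, na = stats_[a]
        mb, s2b, nb = stats_[b]
        diff = ma - mb
        spread = np.sqrt(s2a / na + s2b / nb)
        if spread == 0:
            lo = hi = diff
        else:
            nu = _welch_df(s2a, na, s2b, nb)
            q = studentized_range.ppf(1.0 - alpha, J, nu)
            hw = q / np.sqrt(2.0) * spread
            lo, hi = diff - hw, diff + hw
        intervals[(a, b)] = (lo, hi)
        if hi < 0:
            wins[a] += 1
        elif lo > 0:
            wins[b] += 1

    max_wins = max(wins.values())
    superior = tuple(name for name in methods if wins[name] == max_wins)
    return ComparisonOutcome(p=p, wins=wins, superior_set=superior, intervals=intervals)


def sum_wins(
    outcomes: list[ComparisonOutcome], prange: tuple[int, int]
) -> dict[str, int]:
    """Element-wise win totals over proportions in the closed range."""
    lo, hi = prange
    selected = [o for o in outcomes if lo <= o.p <= hi]
    if not selected:
        raise ValueError(f"no comparison outcomes in range [{lo}, {hi}]")
    totals: dict[str, int] = {}
    for o in selected:
        for name, w in o.wins.items():
            totals[name] = totals.get(name, 0) + w
    return totals
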