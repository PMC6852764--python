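"""Independence approximation for equal-frequency detection probabilities.

An earlier approach to the "how many cells" question treats the k
subpopulation counts as independent binomials with a common frequency f,
giving P(all detected) = P(Binomial(n, f) >= c)^k.  The counts are in fact
negatively correlated (they share the n draws), so this slightly
overestimates the probability and can understate the required cell count.
This module implements the approximation and a side-by-side comparison with
the exact multinomial calculation.
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd
from scipy.stats import binom

from .errors import TargetUnreachableError
from .sample_size import DEFAULT_MAX_N, prospective_design

__all__ = ["prob_all_detected_indep", "invert_indep", "comparison_table"]


def prob_all_detected_indep(n: int, f: float, k: int, c: int) -> float:
    """P(N >= c)^k with N ~ Binomial(n, f), computed in log space."""
    if not 0 < f <= 1:
        raise ValueError("frequency f must be in (0, 1]")
    if k * f > 1.0 + 1e-9:
        raise ValueError(f"k*f = {k * f:.6g} exceeds 1")
    if c <= 0:
        return 1.0
    if n < c:
        return 0.0
    # logsf(c-1) = log P(N > c-1) = log P(N >= c)
    log_tail = float(binom.logsf(c - 1, n, f))
    if log_tail == -math.inf:
        return 0.0
    return math.exp(k * log_tail)


def invert_indep(
    f: float, k: int, c: int, p_star: float, max_n: int = DEFAULT_MAX_N
) -> int:
    """Smallest n with prob_all_detected_indep(n, f, k, c) >= p_star."""
    if not 0.0 < p_star < 1.0:
        raise ValueError("p_star must be in (0, 1)")
    if c <= 0:
        return 0
    lo, hi = c - 1, max(c, 1)  # prob(lo) = 0 < p_star
    while prob_all_detected_indep(hi, f, k, c) < p_star:
        lo = hi
        if hi >= max_n:
            raise TargetUnreachableError(
                f"independence approximation never reaches {p_star} by n={max_n}"
            )
        hi = min(hi * 2, max_n)
    while hi > lo + 1:
        mid = (lo + hi) // 2
        if prob_all_detected_indep(mid, f, k, c) >= p_star:
            hi = mid
        else:
            lo = mid
    return hi


def comparison_table(
    scenarios: Sequence[tuple[float, int]],
    c: int = 10,
    p_star: float = 0.95,
    method: str = "auto",
) -> pd.DataFrame:
    """Exact vs independence-approximation required cells per (f, k) scenario.

    Returns a DataFrame with columns ``frequency``, ``k``, ``n_exact``,
    ``n_approx``.  The exact column uses the full multinomial calculation
    (with an unconstrained remainder category when k*f < 1); the approximate
    column uses the equal-frequency independent-binomial shortcut.
    """
    rows = []
    for f, k in scenarios:
        design = prospective_design(
            rarest_freq=f, num_rare=k, c=c, p_star=p_star,
            curve_span=0, method=method,
        )
        rows.append(
            {
                "frequency": f,
                "k": k,
                "n_exact": design.n_star,
                "n_approx": invert_indep(f, k, c, p_star),
            }
        )
    return pd.DataFrame(rows, columns=["frequency", "k", "n_exact", "n_approx"])
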