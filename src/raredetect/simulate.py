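"""Ground-truth oracles and synthetic scenario generation for validation.

Everything here is deliberately independent of the truncated-Poisson code
path: the brute-force calculator enumerates multinomial outcomes directly,
and the Monte-Carlo estimator samples count vectors.  They exist to check
the fast calculation, not to be fast themselves.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np
from scipy.special import gammaln

from .multinomial import BoundsSpec, FrequencyVector

__all__ = [
    "brute_force_pmultinom",
    "sample_multinomial",
    "monte_carlo_event_probability",
    "random_scenario",
    "random_moderate_event",
]

_MAX_COMPOSITIONS = 1_000_000


def _compositions(n: int, k: int) -> Iterator[tuple[int, ...]]:
    """All k-tuples of nonnegative integers summing to n, lexicographically."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


def brute_force_pmultinom(
    bounds: BoundsSpec, size: int, probs: FrequencyVector
) -> float:
    """Rectangular multinomial probability by exhaustive enumeration.

    Sums the multinomial pmf (log-space coefficients) over every composition
    of ``size`` into k parts that satisfies the bounds.  Guarded against
    combinatorial blow-up; intended for small validation instances only.
    """
    n, k = int(size), len(probs)
    if math.comb(n + k - 1, k - 1) > _MAX_COMPOSITIONS:
        raise ValueError(
            f"instance too large to enumerate: C({n + k - 1},{k - 1}) compositions"
        )
    p = probs.probs
    # zero-frequency categories are skipped whenever x_i > 0, so a placeholder
    # log-probability of 0 for them never enters a retained term
    logp = np.where(p > 0, np.log(np.maximum(p, 1e-300)), 0.0)
    lo, hi = bounds.lower, bounds.upper
    total = 0.0
    log_nfact = gammaln(n + 1)
    for counts in _compositions(n, k):
        x = np.asarray(counts)
        if np.any(x <= lo) or np.any(x > hi):
            continue
        if np.any((x > 0) & (p == 0)):
            continue
        ll = log_nfact - gammaln(x + 1).sum() + float(np.dot(x, logp))
        total += math.exp(ll)
    return min(total, 1.0)


def sample_multinomial(
    n: int, probs: FrequencyVector, n_reps: int, seed: int
) -> np.ndarray:
    """Seeded multinomial count draws; one row of k counts per repetition."""
    rng = np.random.default_rng(seed)
    return rng.multinomial(n, probs.probs, size=n_reps)


def monte_carlo_event_probability(
    n: int,
    probs: FrequencyVector,
    bounds: BoundsSpec,
    n_reps: int,
    seed: int,
) -> tuple[float, float]:
    """Fraction of simulated count vectors inside the rectangular event.

    Returns ``(estimate, standard_error)`` with the binomial standard error
    sqrt(p_hat (1 - p_hat) / n_reps).
    """
    counts = sample_multinomial(n, probs, n_reps, seed)
    inside = np.all((counts > bounds.lower) & (counts <= bounds.upper), axis=1)
    p_hat = float(np.mean(inside))
    se = math.sqrt(p_hat * (1.0 - p_hat) / n_reps)
    return p_hat, se


def random_scenario(
    seed: int, k_max: int = 3, n_max: int = 40
) -> tuple[FrequencyVector, BoundsSpec, int]:
    """Randomized small test instance: frequencies, lower bounds, sample size.

    Frequencies are uniform on the simplex (flat Dirichlet); lower bounds
    are drawn so the event is always satisfiable (sum of minimal counts does
    not exceed n) and at least one category is genuinely constrained.
    """
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, k_max + 1))
    n = int(rng.integers(5, n_max + 1))
    probs = FrequencyVector(rng.dirichlet(np.ones(k)))
    while True:
        # a_i = c_i - 1 with c_i in {0, ..., ~n/k}; -1 means unconstrained
        c = rng.integers(0, max(n // k, 2) + 1, size=k)
        if 0 < c.sum() <= n:
            break
    return probs, BoundsSpec(lower=c.astype(float) - 1.0), n


def random_moderate_event(
    seed: int, k_max: int = 4, n_max: int = 60
) -> tuple[FrequencyVector, BoundsSpec, int]:
    """Randomized detection event whose probability avoids the extremes.

    Monte-Carlo validation needs events the simulation can actually resolve:
    the binomial standard error degenerates when the empirical rate hits 0 or
    1.  Requirements are therefore drawn at or below each category's expected
    count, and the first category's requirement is pinned *at* its mean so
    the joint probability stays away from both 0 and 1 by construction (its
    marginal tail is roughly one half).
    """
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, k_max + 1))
    n = int(rng.integers(20, n_max + 1))
    probs = FrequencyVector(rng.dirichlet(np.full(k, 3.0)))
    means = n * probs.probs
    c = np.floor(means * rng.uniform(0.0, 0.9, size=k)).astype(int)
    c[0] = max(int(means[0]), 1)
    return probs, BoundsSpec(lower=c.astype(float) - 1.0), n
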