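"""Bayesian uncertainty for retrospective sample-size calculations.

After an experiment, subpopulation frequencies are only estimated — n_i
cells observed from population i out of a total N.  With the improper
Dirichlet(0, ..., 0) prior (appropriate when the set of possible outcomes is
not known in advance), the posterior over frequencies is Dirichlet(n_1, ...,
n_k), proper as long as every observed count is positive.  Posterior draws
are pushed through the detection-probability and required-sample-size
calculations to produce one-sided credible bounds: a *lower* bound on the
probability of detecting all subpopulations again, and an *upper* bound on
the number of cells a replicate experiment would need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CountsTableError
from .multinomial import BoundsSpec, FrequencyVector, pmultinom
from .sample_size import DEFAULT_MAX_N, invert_pmultinom

__all__ = [
    "CountsTable",
    "CredibleSummary",
    "RetrospectiveReport",
    "dirichlet_posterior_draws",
    "posterior_probability_lower_bound",
    "posterior_required_n_upper_bound",
    "retrospective_report",
]

DEFAULT_DRAWS = 10_000
DEFAULT_LEVEL = 0.95


@dataclass(frozen=True)
class CountsTable:
    """Observed cells per subpopulation from a previous experiment."""

    names: tuple[str, ...]
    counts: np.ndarray

    def __init__(self, counts: Sequence[int], names: Sequence[str] | None = None):
        arr = np.asarray(counts, dtype=int)
        if arr.ndim != 1 or arr.size < 1:
            raise CountsTableError("counts must form a nonempty 1-D vector")
        if np.any(arr < 1):
            raise CountsTableError(
                "every observed subpopulation needs at least one cell: the "
                "Dirichlet(0,...,0) prior gives a proper posterior only for "
                "positive counts"
            )
        if names is None:
            names = tuple(f"subpop{i + 1}" for i in range(arr.size))
        names = tuple(str(x) for x in names)
        if len(names) != arr.size:
            raise CountsTableError("names and counts lengths differ")
        if len(set(names)) != len(names):
            raise CountsTableError("subpopulation names must be unique")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return int(self.counts.size)

    def empirical_frequencies(self) -> FrequencyVector:
        return FrequencyVector(self.counts / self.total)


@dataclass(frozen=True)
class CredibleSummary:
    """Point estimate with a one-sided posterior credible bound."""

    point_estimate: float
    one_sided_bound: float
    level: float
    n_draws: int
    seed: int


def dirichlet_posterior_draws(
    counts: CountsTable, n_draws: int, seed: int
) -> np.ndarray:
    """Draws from the Dirichlet(n_1, ..., n_k) posterior over frequencies.

    Implemented as independent Gamma(n_i, 1) variates normalized by their
    sum; seeded and reproducible.  Returns an (n_draws, k) matrix whose rows
    sum to 1.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    gammas = rng.gamma(shape=counts.counts.astype(float), size=(n_draws, counts.k))
    return gammas / gammas.sum(axis=1, keepdims=True)


def _integer_upper_quantile(values: np.ndarray, level: float) -> int:
    """Smallest value holding at least ``level`` posterior mass at or below it."""
    s = np.sort(values)
    idx = max(int(math.ceil(level * s.size)), 1) - 1
    return int(s[idx])


def posterior_probability_lower_bound(
    counts: CountsTable,
    c: int,
    n: int,
    level: float = DEFAULT_LEVEL,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
    *,
    draws: np.ndarray | None = None,
) -> CredibleSummary:
    """Lower credible bound for P(all subpopulations yield >= c cells at size n).

    The point estimate evaluates the probability at the empirical
    frequencies; the bound is the empirical (1 - level) quantile of the
    probability over posterior frequency draws (linear interpolation).
    """
    bounds = BoundsSpec.at_least(c, counts.k)
    point = pmultinom(bounds, n, counts.empirical_frequencies())
    if draws is None:
        draws = dirichlet_posterior_draws(counts, n_draws, seed)
    probs = np.array(
        [pmultinom(bounds, n, FrequencyVector(row)) for row in draws]
    )
    lower = float(np.quantile(probs, 1.0 - level))
    return CredibleSummary(
        point_estimate=point,
        one_sided_bound=lower,
        level=level,
        n_draws=int(draws.shape[0]),
        seed=seed,
    )


def posterior_required_n_upper_bound(
    counts: CountsTable,
    c: int,
    p_star: float = 0.95,
    level: float = DEFAULT_LEVEL,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
    max_n: int = DEFAULT_MAX_N,
    *,
    draws: np.ndarray | None = None,
) -> CredibleSummary:
    """Upper credible bound for the cells required by a replicate experiment.

    For each posterior frequency draw the required n* is recomputed; the
    bound is the nearest-rank ``level`` quantile (smallest integer with at
    least that much posterior mass at or below it).  Each inversion warm
    starts from the previous draw's n* to amortize the search.
    """
    bounds = BoundsSpec.at_least(c, counts.k)
    point = invert_pmultinom(
        bounds, counts.empirical_frequencies(), p_star, max_n=max_n
    )
    if draws is None:
        draws = dirichlet_posterior_draws(counts, n_draws, seed)
    n_stars = np.empty(draws.shape[0], dtype=int)
    prev = point
    for i, row in enumerate(draws):
        prev = invert_pmultinom(
            bounds, FrequencyVector(row), p_star, max_n=max_n, start=prev
        )
        n_stars[i] = prev
    upper = _integer_upper_quantile(n_stars, level)
    return CredibleSummary(
        point_estimate=point,
        one_sided_bound=upper,
        level=level,
        n_draws=int(draws.shape[0]),
        seed=seed,
    )


@dataclass(frozen=True)
class RetrospectiveReport:
    """Replicate-experiment requirements inferred from observed counts."""

    counts: CountsTable
    c: int
    p_star: float
    n_star: CredibleSummary  # point n* and upper credible bound
    prob_at_sequenced: CredibleSummary  # detection prob at the actual total
    cells_sequenced: int
    oversampled: bool
    curve: np.ndarray  # columns: n, probability, probability_lower
    level: float
    n_draws: int
    seed: int


def retrospective_report(
    counts: CountsTable,
    c: int,
    p_star: float = 0.95,
    level: float = DEFAULT_LEVEL,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
    curve_points: int = 40,
    max_n: int = DEFAULT_MAX_N,
) -> RetrospectiveReport:
    """Full retrospective analysis of a finished experiment.

    Computes the cells required for a hypothetical replicate (point estimate
    and one-sided upper credible bound), the detection probability at the
    number of cells actually sequenced (with its lower bound), and a
    probability curve with a per-n posterior lower-bound column.  A single
    matrix of posterior draws is shared by every summary, so a fixed seed
    yields a byte-identical report.
    """
    draws = dirichlet_posterior_draws(counts, n_draws, seed)
    n_summary = posterior_required_n_upper_bound(
        counts, c, p_star, level, seed=seed, max_n=max_n, draws=draws
    )
    total = counts.total
    p_summary = posterior_probability_lower_bound(
        counts, c, total, level, seed=seed, draws=draws
    )
    n_hi = int(
        max(n_summary.one_sided_bound, n_summary.point_estimate, total) * 1.25
    )
    n_lo = c * counts.k
    grid = np.unique(np.linspace(n_lo, max(n_hi, n_lo + 1), curve_points).astype(int))
    bounds = BoundsSpec.at_least(c, counts.k)
    emp = counts.empirical_frequencies()
    curve = np.empty((grid.size, 3))
    for j, n in enumerate(grid):
        probs = np.array(
            [pmultinom(bounds, int(n), FrequencyVector(row)) for row in draws]
        )
        curve[j] = (
            n,
            pmultinom(bounds, int(n), emp),
            float(np.quantile(probs, 1.0 - level)),
        )
    return RetrospectiveReport(
        counts=counts,
        c=c,
        p_star=p_star,
        n_star=n_summary,
        prob_at_sequenced=p_summary,
        cells_sequenced=total,
        oversampled=total >= n_summary.point_estimate,
        curve=curve,
        level=level,
        n_draws=n_draws,
        seed=seed,
    )
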