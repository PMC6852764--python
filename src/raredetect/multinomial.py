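"""Rectangular multinomial probabilities via the truncated-Poisson product.

The central quantity is P(a_i < N_i <= b_i for all i) for a multinomial
count vector N ~ Multinomial(p, n) — for experiment planning, the probability
of sampling more than a_i cells from every subpopulation i.  Conditioning
independent Poissons X_i ~ Poisson(alpha * p_i) on their sum being n turns
this rectangular probability into

    P(N in E) = prod_i P(a_i < X_i <= b_i)
                * P(sum_i X_i^(a_i,b_i) = n) / P(sum_i X_i = n),

where X_i^(a_i,b_i) is X_i conditioned on the interval (a_i, b_i].  The
identity holds for any alpha > 0; we fix alpha = n so the denominator — a
Poisson(alpha) pmf evaluated at n — sits at its mode, maximizing numerical
headroom.  The numerator sum pmf is computed either exactly (FFT convolution
of the component pmfs) or by an Edgeworth series for large n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .edgeworth import edgeworth_sum_mass_at
from .errors import EdgeworthDivergenceError, ImpossibleConstraintError
from .lattice import (
    LatticePMF,
    TruncatedPoissonSpec,
    log_convolve_sum_mass_at,
    poisson_logpmf,
    truncated_poisson_pmf,
)

__all__ = ["FrequencyVector", "BoundsSpec", "pmultinom", "CONVOLUTION_MAX_N"]

#: Default method="auto" switch point: exact convolution at or below this n,
#: Edgeworth series above.  Convolution is O(k n log n), comfortably
#: interactive up to this size.
CONVOLUTION_MAX_N = 20_000

_SUM_TOL = 1e-9

Method = Literal["exact", "approximate", "auto"]


@dataclass(frozen=True)
class FrequencyVector:
    """Subpopulation frequencies p_1..p_k (the multinomial probability vector)."""

    probs: np.ndarray

    def __init__(self, probs: Sequence[float]) -> None:
        arr = np.asarray(probs, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("frequencies must form a nonempty 1-D vector")
        if np.any(arr < 0):
            raise ValueError("frequencies must be nonnegative")
        if abs(float(arr.sum()) - 1.0) > _SUM_TOL:
            raise ValueError(
                f"frequencies must sum to 1 (got {float(arr.sum()):.12g})"
            )
        object.__setattr__(self, "probs", arr)

    def __len__(self) -> int:
        return int(self.probs.size)


@dataclass(frozen=True)
class BoundsSpec:
    """Per-category bounds defining the rectangular event a_i < N_i <= b_i.

    ``lower`` entries are strict lower bounds; -1 (or any negative value)
    means unconstrained below.  ``upper`` entries are inclusive; ``inf``
    means unconstrained above.  "At least c cells from category i" is encoded
    as ``lower[i] = c - 1``.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __init__(
        self,
        lower: Sequence[float] | None = None,
        upper: Sequence[float] | None = None,
        k: int | None = None,
    ) -> None:
        if lower is None and upper is None:
            raise ValueError("at least one of lower/upper must be supplied")
        if lower is None:
            up = np.asarray(upper, dtype=float)
            lo = np.full(up.size, -1.0)
        elif upper is None:
            lo = np.asarray(lower, dtype=float)
            up = np.full(lo.size, math.inf)
        else:
            lo = np.asarray(lower, dtype=float)
            up = np.asarray(upper, dtype=float)
        if lo.shape != up.shape or lo.ndim != 1 or lo.size < 1:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if k is not None and lo.size != k:
            raise ValueError(f"bounds have length {lo.size}, expected {k}")
        for a, b in zip(lo, up):
            if math.isfinite(a) and a != int(a):
                raise ValueError("finite lower bounds must be integers")
            if math.isfinite(b) and b != int(b):
                raise ValueError("finite upper bounds must be integers")
            if math.isfinite(b) and a >= b:
                raise ValueError(f"need lower < upper per category, got ({a}, {b}]")
        lo = np.where(np.isfinite(lo), lo, -1.0)
        lo = np.maximum(lo, -1.0)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)

    @classmethod
    def at_least(cls, c: int | Sequence[int], k: int) -> "BoundsSpec":
        """Event "at least c cells in each of the k categories"."""
        c_arr = np.broadcast_to(np.asarray(c, dtype=float), (k,))
        return cls(lower=c_arr - 1.0)

    def __len__(self) -> int:
        return int(self.lower.size)

    @property
    def lower_only(self) -> bool:
        return bool(np.all(np.isinf(self.upper)))

    def contains_zero_vector(self) -> bool:
        return bool(np.all(self.lower < 0) and np.all(self.upper >= 0))


def _component_specs(
    bounds: BoundsSpec, probs: FrequencyVector, alpha: float
) -> list[TruncatedPoissonSpec] | None:
    """Truncated-Poisson components for the constrained categories.

    Returns None when some zero-frequency category carries a lower bound
    (the event then has probability 0).  Zero-frequency categories without a
    lower bound are dropped: their count is identically 0, inside (a, b].
    """
    specs = []
    for p_i, a, b in zip(probs.probs, bounds.lower, bounds.upper):
        if p_i == 0.0:
            if a >= 0:
                return None
            continue
        specs.append(
            TruncatedPoissonSpec(
                rate=alpha * p_i, lower_excl=int(a), upper_incl=float(b)
            )
        )
    return specs


def _log_sum_mass_exact(specs: list[TruncatedPoissonSpec], n: int) -> float:
    components: list[LatticePMF] = []
    for spec in specs:
        if spec.min_support > n:
            return -math.inf
        components.append(truncated_poisson_pmf(spec, cap=n))
    return log_convolve_sum_mass_at(components, n)


def pmultinom(
    bounds: BoundsSpec,
    size: int,
    probs: FrequencyVector,
    method: Method = "auto",
    *,
    _alpha: float | None = None,
) -> float:
    """Probability that Multinomial(probs, size) falls in the rectangular event.

    Parameters
    ----------
    bounds
        Strict lower / inclusive upper bounds per category.
    size
        Number of multinomial draws n (cells sequenced).
    probs
        Category frequencies.
    method
        "exact" uses FFT convolution for the truncated-sum pmf; "approximate"
        uses the Edgeworth series (falling back to convolution if it
        diverges); "auto" switches at n = ``CONVOLUTION_MAX_N``.
    _alpha
        Internal override of the Poissonization constant (default n); the
        result is invariant to it, which tests exploit.

    Returns
    -------
    float
        P(a_i < N_i <= b_i for all i), clamped to [0, 1].
    """
    if size < 0:
        raise ValueError("size must be >= 0")
    if len(bounds) != len(probs):
        raise ValueError(
            f"bounds ({len(bounds)}) and probs ({len(probs)}) lengths differ"
        )
    if method not in ("exact", "approximate", "auto"):
        raise ValueError(f"unknown method {method!r}")
    n = int(size)
    if n == 0:
        return 1.0 if bounds.contains_zero_vector() else 0.0
    if np.all(bounds.lower < 0) and np.all(np.isinf(bounds.upper)):
        return 1.0  # whole sample space

    alpha = float(n) if _alpha is None else float(_alpha)
    specs = _component_specs(bounds, probs, alpha)
    if specs is None:
        return 0.0
    if not specs:  # every category unconstrained with zero frequency removed
        return 1.0
    if sum(s.min_support for s in specs) > n:
        return 0.0  # pigeonhole: lower bounds alone exceed the sample size
    try:
        log_tails = sum(s.log_interval_mass() for s in specs)
    except ImpossibleConstraintError:
        return 0.0

    use_edgeworth = method == "approximate" or (
        method == "auto" and n > CONVOLUTION_MAX_N
    )
    log_num: float
    if use_edgeworth:
        try:
            num = edgeworth_sum_mass_at(specs, n)
            log_num = math.log(num) if num > 0 else -math.inf
        except EdgeworthDivergenceError:
            log_num = _log_sum_mass_exact(specs, n)
    else:
        log_num = _log_sum_mass_exact(specs, n)
    if log_num == -math.inf:
        return 0.0

    log_den = float(poisson_logpmf(n, alpha))
    log_prob = log_tails + log_num - log_den
    return min(max(math.exp(log_prob), 0.0), 1.0)
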