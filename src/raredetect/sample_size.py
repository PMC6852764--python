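"""Sample-size inversion: how many cells to sequence.

Given per-category detection requirements ("at least c cells from each
subpopulation of interest"), the detection probability is nondecreasing in
the number of cells sequenced, so the required sample size

    n* = min { n : P(N_1 >= c, ..., N_k >= c) >= p* }

is found by exponential bracketing followed by binary search.  The
prospective design helper builds the frequency vector a researcher specifies
before an experiment: k subpopulations at the rarest frequency f, optional
extras at higher frequencies, and an unconstrained remainder category
absorbing the rest of the population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import NonMonotoneInversionError, TargetUnreachableError
from .multinomial import BoundsSpec, FrequencyVector, Method, pmultinom

__all__ = [
    "DetectionEvent",
    "DesignResult",
    "invert_pmultinom",
    "prospective_design",
    "probability_curve",
]

_REMAINDER_EPS = 1e-9
DEFAULT_MAX_N = 1_000_000


@dataclass(frozen=True)
class DetectionEvent:
    """"At least c representatives" requirement over the constrained categories.

    ``c`` may be a scalar (uniform requirement) or a per-category vector over
    the constrained categories.  ``constrained_mask`` marks which categories
    of the frequency vector carry the requirement; a trailing remainder
    category is typically unconstrained.
    """

    c: int | Sequence[int]
    constrained_mask: np.ndarray

    def __init__(self, c: int | Sequence[int], constrained_mask: Sequence[bool]) -> None:
        mask = np.asarray(constrained_mask, dtype=bool)
        if not mask.any():
            raise ValueError("at least one category must be constrained")
        c_arr = np.asarray(c, dtype=int)
        if np.any(c_arr < 0):
            raise ValueError("required representatives c must be >= 0")
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "constrained_mask", mask)

    def bounds(self) -> BoundsSpec:
        k = self.constrained_mask.size
        lower = np.full(k, -1.0)
        lower[self.constrained_mask] = np.asarray(self.c, dtype=float) - 1.0
        return BoundsSpec(lower=lower)


@dataclass(frozen=True)
class DesignResult:
    """Required sample size with its probability curve and parameter echo."""

    n_star: int
    p_star: float
    curve: list[tuple[int, float]]
    frequencies: np.ndarray
    c: int
    rarest_freq: float | None = None
    num_rare: int | None = None

    def curve_array(self) -> np.ndarray:
        return np.asarray(self.curve, dtype=float)


def _check_lower_only(bounds: BoundsSpec) -> None:
    if not bounds.lower_only:
        raise NonMonotoneInversionError(
            "sample-size inversion requires lower-bound-only events; finite "
            "upper bounds make the probability non-monotone in n"
        )


def invert_pmultinom(
    bounds: BoundsSpec,
    probs: FrequencyVector,
    target_prob: float,
    method: Method = "auto",
    max_n: int = DEFAULT_MAX_N,
    *,
    start: int | None = None,
) -> int:
    """Smallest n with pmultinom(bounds, n, probs) >= target_prob.

    Valid for lower-bound-only (detection) events, whose probability is
    nondecreasing in n.  Exponential bracketing from the pigeonhole minimum
    (or from ``start``, e.g. a previous solution) is followed by binary
    search.

    Raises
    ------
    NonMonotoneInversionError
        If any finite upper bound is present.
    TargetUnreachableError
        If no n <= max_n reaches the target, naming the rarest constrained
        category as the likely bottleneck.
    """
    if not 0.0 < target_prob < 1.0:
        raise ValueError("target_prob must be in (0, 1)")
    _check_lower_only(bounds)

    def prob(n: int) -> float:
        return pmultinom(bounds, n, probs, method=method)

    n0 = int(np.sum(np.maximum(bounds.lower + 1, 0)))
    if n0 == 0:
        n0 = 0 if prob(0) >= target_prob else 1
        if n0 == 0:
            return 0

    constrained = bounds.lower >= 0
    if np.any(probs.probs[constrained] == 0.0):
        i = int(np.argmin(np.where(constrained, probs.probs, np.inf)))
        raise TargetUnreachableError(
            f"category {i} has frequency 0 but a lower bound; the event has "
            "probability 0 for every n"
        )

    # Exponential bracketing.
    lo = n0 - 1  # prob(lo) < target by pigeonhole (or by the n0=1 probe above)
    hi = max(n0, 1) if start is None else max(int(start), n0, 1)
    while prob(hi) < target_prob:
        lo = hi
        if hi >= max_n:
            i = int(np.argmin(np.where(constrained, probs.probs, np.inf)))
            raise TargetUnreachableError(
                f"target probability {target_prob} not reached by n={max_n}; "
                f"limiting category is {i} (frequency {probs.probs[i]:.4g})"
            )
        hi = min(hi * 2, max_n)
    # Shrink below a warm start that overshot.
    while hi > lo + 1:
        mid = (lo + hi) // 2
        if prob(mid) >= target_prob:
            hi = mid
        else:
            lo = mid
    return hi


def probability_curve(
    probs: FrequencyVector,
    event: DetectionEvent,
    n_from: int,
    n_to: int,
    method: Method = "auto",
) -> list[tuple[int, float]]:
    """Detection probability on the inclusive integer grid [n_from, n_to]."""
    if n_from > n_to:
        raise ValueError("n_from must be <= n_to")
    bounds = event.bounds()
    return [
        (n, pmultinom(bounds, n, probs, method=method))
        for n in range(int(n_from), int(n_to) + 1)
    ]


def build_frequency_vector(
    rarest_freq: float,
    num_rare: int,
    extra_freqs: Sequence[float] = (),
) -> tuple[FrequencyVector, np.ndarray]:
    """Frequency vector (rare copies + extras + remainder) and constrained mask."""
    from .errors import FrequencyBudgetError

    if rarest_freq <= 0:
        raise ValueError("rarest frequency must be positive")
    if num_rare < 1:
        raise ValueError("need at least one rare subpopulation")
    extras = [float(f) for f in extra_freqs]
    if any(f <= 0 for f in extras):
        raise ValueError("extra frequencies must be positive")
    total = num_rare * rarest_freq + sum(extras)
    if total > 1.0 + _REMAINDER_EPS:
        raise FrequencyBudgetError(
            f"frequencies sum to {total:.6g} > 1 "
            f"({num_rare} x {rarest_freq} plus extras {extras})"
        )
    freqs = [rarest_freq] * num_rare + extras
    remainder = 1.0 - total
    if remainder > _REMAINDER_EPS:
        freqs.append(remainder)
        mask = np.array([True] * (num_rare + len(extras)) + [False])
    else:
        # Frequencies already sum to one; rescale away the tolerance slack.
        freqs = list(np.asarray(freqs) / sum(freqs))
        mask = np.full(len(freqs), True)
    return FrequencyVector(freqs), mask


def prospective_design(
    rarest_freq: float,
    num_rare: int,
    extra_freqs: Sequence[float] = (),
    c: int = 10,
    p_star: float = 0.95,
    curve_span: int | None = None,
    method: Method = "auto",
    max_n: int = DEFAULT_MAX_N,
) -> DesignResult:
    """Required cells to detect ``num_rare`` subpopulations at frequency f.

    Builds the frequency vector as ``num_rare`` copies of ``rarest_freq``,
    any extra (higher) frequencies, and one unconstrained remainder category;
    every non-remainder category must yield at least ``c`` cells.  Returns
    the minimal n* reaching probability ``p_star`` plus a probability curve
    extending ``curve_span`` cells past n* (default: 25% of n*).
    """
    probs, mask = build_frequency_vector(rarest_freq, num_rare, extra_freqs)
    event = DetectionEvent(c=c, constrained_mask=mask)
    bounds = event.bounds()
    n_star = invert_pmultinom(bounds, probs, p_star, method=method, max_n=max_n)
    if curve_span is None:
        curve_span = max(int(round(0.25 * n_star)), 5)
    n0 = int(np.sum(np.maximum(bounds.lower + 1, 0)))
    curve = probability_curve(probs, event, n0, n_star + curve_span, method=method)
    return DesignResult(
        n_star=n_star,
        p_star=p_star,
        curve=curve,
        frequencies=probs.probs,
        c=c,
        rarest_freq=rarest_freq,
        num_rare=num_rare,
    )
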