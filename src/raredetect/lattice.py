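"""Truncated-Poisson components and exact lattice convolution.

A rectangular multinomial probability factors into a product of Poisson
interval masses times a ratio of two sum pmf values.  The numerator of that
ratio is the pmf of a sum of independent *truncated* Poisson variables,
each conditioned to lie in an interval (a_i, b_i].  This module represents
those component distributions on the nonnegative integer lattice and
computes the sum's mass at a target point exactly, by sequential FFT
convolution carried out with per-array log scaling to avoid underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import gammaln, logsumexp, pdtrc

from .errors import ImpossibleConstraintError

__all__ = [
    "TruncatedPoissonSpec",
    "LatticePMF",
    "truncated_poisson_pmf",
    "convolve_sum_mass_at",
    "log_convolve_sum_mass_at",
]

# FFT round-off can leave small negative entries where the true value is ~0.
# Anything more negative than this (relative to the array peak of 1) means a
# genuine numerical problem rather than benign round-off.
_FFT_NEGATIVE_TOL = 1e-12


def poisson_logpmf(k: np.ndarray | int, rate: float) -> np.ndarray | float:
    """log Poisson(rate) pmf at integer(s) k, via the gamma function directly.

    Avoids the per-call overhead of the generic scipy distribution machinery;
    this sits on the innermost loop of every probability evaluation.
    """
    k_arr = np.asarray(k, dtype=float)
    return k_arr * math.log(rate) - rate - gammaln(k_arr + 1.0)


def _poisson_logsf(k: float, rate: float) -> float:
    """log P(X > k) for X ~ Poisson(rate); k may be -1 (whole line)."""
    if k < 0:
        return 0.0
    sf = float(pdtrc(k, rate))  # regularized upper incomplete gamma
    if sf > 1e-290:
        return math.log(sf)
    # Deep tail: sum pmf terms from k+1 until they stop mattering.
    j = np.arange(k + 1, max(k + 1, rate) + 20 * math.sqrt(rate) + 20)
    return float(logsumexp(poisson_logpmf(j, rate)))


@dataclass(frozen=True)
class TruncatedPoissonSpec:
    """A Poisson(rate) variable conditioned on ``lower_excl < X <= upper_incl``.

    ``lower_excl`` is a strict lower bound (use -1 for "no lower bound");
    ``upper_incl`` is inclusive (use ``math.inf`` for "no upper bound").
    """

    rate: float
    lower_excl: int = -1
    upper_incl: float = math.inf

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"Poisson rate must be >= 0, got {self.rate}")
        if math.isfinite(self.upper_incl):
            if self.upper_incl != int(self.upper_incl):
                raise ValueError("finite upper bound must be an integer")
            if self.lower_excl >= self.upper_incl:
                raise ValueError(
                    f"empty truncation interval ({self.lower_excl}, {self.upper_incl}]"
                )

    @property
    def min_support(self) -> int:
        """Smallest integer the truncated variable can take."""
        return max(self.lower_excl + 1, 0)

    def log_interval_mass(self) -> float:
        """log P(lower_excl < X <= upper_incl) for the *untruncated* Poisson.

        Memoized on the instance (it is needed both to normalize the
        component pmf and in the probability product).  Raises
        :class:`ImpossibleConstraintError` when the interval mass is zero
        (e.g. rate 0 with a positive lower bound).
        """
        cached = self.__dict__.get("_log_interval_mass")
        if cached is not None:
            return cached
        a, b = self.lower_excl, self.upper_incl
        if self.rate == 0.0:
            # Degenerate at 0: interval mass is 1 iff 0 lies in (a, b].
            if a < 0 <= b:
                return 0.0
            raise ImpossibleConstraintError(
                f"Poisson rate 0 cannot satisfy ({a}, {b}]"
            )
        if not math.isfinite(b):
            logmass = _poisson_logsf(a, self.rate)
        else:
            # sf difference is accurate unless both tails nearly cancel;
            # fall back to direct summation of the pmf in that case.
            mass = float(pdtrc(a, self.rate)) - float(pdtrc(b, self.rate)) \
                if a >= 0 else 1.0 - float(pdtrc(b, self.rate))
            if mass > 1e-290:
                logmass = math.log(mass)
            else:
                lo, hi = max(a + 1, 0), int(b)
                logmass = float(
                    logsumexp(poisson_logpmf(np.arange(lo, hi + 1), self.rate))
                )
        if logmass == -math.inf:
            raise ImpossibleConstraintError(
                f"zero probability in interval ({a}, {b}] for rate {self.rate}"
            )
        object.__setattr__(self, "_log_interval_mass", float(logmass))
        return float(logmass)


@dataclass
class LatticePMF:
    """A mass function on consecutive nonnegative integers.

    True mass at ``offset + j`` is ``masses[j] * exp(log_scale)``.  Arrays are
    kept max-normalized (largest stored entry 1) with the balance carried in
    ``log_scale`` so that long convolution chains never underflow.
    """

    offset: int
    masses: np.ndarray
    log_scale: float = 0.0

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.ndim != 1 or self.masses.size == 0:
            raise ValueError("masses must be a nonempty 1-D array")
        if np.any(self.masses < 0):
            raise ValueError("masses must be nonnegative")

    def mass_at(self, value: int) -> float:
        """True probability mass at ``value`` (0 outside the support)."""
        j = value - self.offset
        if j < 0 or j >= self.masses.size:
            return 0.0
        return float(self.masses[j] * math.exp(self.log_scale))

    def log_mass_at(self, value: int) -> float:
        j = value - self.offset
        if j < 0 or j >= self.masses.size or self.masses[j] == 0.0:
            return -math.inf
        return float(math.log(self.masses[j]) + self.log_scale)

    def total_mass(self) -> float:
        return float(np.sum(self.masses) * math.exp(self.log_scale))


def truncated_poisson_pmf(spec: TruncatedPoissonSpec, cap: int) -> LatticePMF:
    """Mass function of a truncated Poisson on ``{max(a+1,0), ..., min(b, cap)}``.

    Normalization uses the *full* interval mass P(a < X <= b), not the mass of
    the capped support, so any mass above ``cap`` is genuinely discarded.  When
    the sum of several such components is later evaluated at a target <= cap,
    dropping that mass is exact: components are nonnegative, so outcomes above
    the cap cannot contribute to the sum at the target.

    Raises
    ------
    ImpossibleConstraintError
        If the truncation interval carries zero mass.
    ValueError
        If ``cap`` is negative or the capped support is empty.
    """
    if cap < 0:
        raise ValueError(f"cap must be >= 0, got {cap}")
    log_tail = spec.log_interval_mass()  # raises on zero-mass intervals
    if spec.rate == 0.0:
        # All mass at 0 (the interval check passed, so 0 is admissible).
        return LatticePMF(offset=0, masses=np.array([1.0]), log_scale=0.0)
    lo = spec.min_support
    hi = min(spec.upper_incl, cap)
    if lo > hi:
        raise ValueError(
            f"support empty under cap={cap}: lower bound forces values > cap"
        )
    support = np.arange(lo, int(hi) + 1)
    logm = poisson_logpmf(support, spec.rate) - log_tail
    peak = float(np.max(logm))
    if peak == -math.inf:
        # Whole capped support is numerically massless (all mass above cap);
        # keep a single zero entry so convolution correctly yields 0.
        return LatticePMF(offset=lo, masses=np.zeros(support.size), log_scale=0.0)
    return LatticePMF(offset=lo, masses=np.exp(logm - peak), log_scale=peak)


def _convolve_pair(x: LatticePMF, y: LatticePMF, target: int) -> LatticePMF:
    """FFT-convolve two lattice pmfs, truncating support above ``target``."""
    arr = fftconvolve(x.masses, y.masses)
    offset = x.offset + y.offset
    # Exact for the mass at any point <= target: summands are nonnegative.
    keep = target - offset + 1
    arr = arr[: max(keep, 1)] if keep >= 1 else arr[:0]
    if arr.size == 0:
        return LatticePMF(offset=offset, masses=np.array([0.0]), log_scale=0.0)
    neg = arr < 0
    if np.any(neg):
        worst = float(arr.min())
        if worst < -_FFT_NEGATIVE_TOL * max(float(arr.max()), 1.0):
            raise FloatingPointError(
                f"FFT convolution produced a large negative mass ({worst})"
            )
        arr = np.where(neg, 0.0, arr)
    peak = float(arr.max())
    if peak == 0.0:
        return LatticePMF(offset=offset, masses=arr, log_scale=0.0)
    return LatticePMF(
        offset=offset,
        masses=arr / peak,
        log_scale=x.log_scale + y.log_scale + math.log(peak),
    )


def log_convolve_sum_mass_at(components: list[LatticePMF], target: int) -> float:
    """log P(sum of components = target), computed by sequential convolution."""
    if not components:
        raise ValueError("need at least one component")
    if target < sum(c.offset for c in components):
        return -math.inf  # pigeonhole: every summand is at least its offset
    acc = components[0]
    for comp in components[1:]:
        acc = _convolve_pair(acc, comp, target)
    return acc.log_mass_at(target)


def convolve_sum_mass_at(components: list[LatticePMF], target: int) -> float:
    """P(X_1 + ... + X_k = target) for independent lattice variables.

    Exact up to floating error; underflow-safe via accumulated log scaling.
    Returns 0.0 when the target is unreachable.
    """
    return float(math.exp(log_convolve_sum_mass_at(components, target)))
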